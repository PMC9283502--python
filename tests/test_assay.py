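"""Virtual PCR-RFLP digest, LCR ligation and direct codon calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kdrmon.assay import (
    AmpliconSpec,
    EnzymeSpec,
    call_codon_variant,
    digest,
    digest_fragments,
    expand_alleles,
    find_amplicon,
    genotype_sample,
    lcr_genotype,
    reverse_complement,
)
from kdrmon.errors import (
    AmbiguityOverflowError,
    AmbiguousPrimingError,
    AmpliconNotFoundError,
    CoverageError,
    DiscordanceError,
)
from kdrmon.loci import KDR_LOCUS, NINE_CLASSES, SKDR_LOCUS
from kdrmon.simulate import Individual, render_sequences, _genotype_from_haplotypes

BSTEII = EnzymeSpec()


def _cohort_of_all_nine():
    """One individual per nine-class genotype, with ground truth."""
    haps = {
        "L/L:M/M": ("LM", "LM"), "L/L:M/I": ("LM", "LI"), "L/L:I/I": ("LI", "LI"),
        "L/F:M/M": ("LM", "FM"), "L/F:M/I": ("LM", "FI"), "L/F:I/I": ("LI", "FI"),
        "F/F:M/M": ("FM", "FM"), "F/F:M/I": ("FM", "FI"), "F/F:I/I": ("FI", "FI"),
    }
    return [
        Individual(cls, pair, _genotype_from_haplotypes(*pair))
        for cls, pair in haps.items()
    ]


# ---------------------------------------------------------------------------
# amplicon finding


def test_find_amplicon_toy_coordinates():
    fwd = "ACGTACGTAC"
    rev_site = "TTGGCCAATT"  # what appears in the template
    template = "G" * 20 + fwd + "CCCCC" + rev_site + "G" * 15
    spec = AmpliconSpec(
        "toy", fwd, reverse_complement(rev_site), 25, (21, 45)
    )
    amp, start, end = find_amplicon(template, spec)
    assert (len(amp), start, end) == (25, 21, 45)
    assert amp == fwd + "CCCCC" + rev_site


def test_find_amplicon_kdr_on_synthetic_reference(reference):
    amp, start, end = find_amplicon(reference.transcript, reference.kdr_amplicon)
    assert len(amp) == 439
    assert (start, end) == reference.kdr_amplicon.reference_interval


def test_find_amplicon_errors():
    fwd = "ACGTACGTAC"
    template = "G" * 20 + fwd + "CCCCC" + "A" * 20
    spec = AmpliconSpec("toy", fwd, "GGGGGGGGGG", 25, (21, 45))
    with pytest.raises(AmpliconNotFoundError):
        find_amplicon(template, spec)
    rev_site = "TTGGCCAATT"
    dup = "G" * 10 + fwd + "CC" + fwd + "CCCCC" + rev_site + "G" * 10
    spec2 = AmpliconSpec("toy2", fwd, reverse_complement(rev_site), 25, (1, 25))
    with pytest.raises(AmbiguousPrimingError):
        find_amplicon(dup, spec2)


def test_find_amplicon_iupac_template_matches_concrete_primer():
    fwd = "ACGTACGTAC"
    rev_site = "TTGGCCAATT"
    template = "G" * 20 + "ACGTAYGTAC" + "CCCCC" + rev_site + "G" * 15
    spec = AmpliconSpec("toy", fwd, reverse_complement(rev_site), 25, (21, 45))
    amp, _, _ = find_amplicon(template, spec)  # Y expands to C, matches
    assert len(amp) == 25


# ---------------------------------------------------------------------------
# allele expansion


def test_expand_alleles():
    assert expand_alleles("ACGT") == ["ACGT"]
    assert sorted(expand_alleles("AYGT")) == ["ACGT", "ATGT"]
    assert len(expand_alleles("RYGT")) == 4
    with pytest.raises(AmbiguityOverflowError):
        expand_alleles("RYR", max_het_sites=2)


# ---------------------------------------------------------------------------
# restriction digest


def test_digest_band_patterns_on_synthetic_amplicons(reference):
    start, end = reference.kdr_amplicon.reference_interval
    wt_amp = reference.transcript[start - 1 : end]
    pos_in_amp = KDR_LOCUS.transcript_position - start  # 0-based
    mut_amp = wt_amp[:pos_in_amp] + "T" + wt_amp[pos_in_amp + 1 :]

    res = digest([wt_amp], BSTEII, KDR_LOCUS)
    assert res.bands == (154, 285) and str(res.call) == "L/L"
    res = digest([mut_amp], BSTEII, KDR_LOCUS)
    assert res.bands == (439,) and str(res.call) == "F/F"
    res = digest([wt_amp, mut_amp], BSTEII, KDR_LOCUS)
    assert res.bands == (154, 285, 439) and str(res.call) == "L/F"


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=10, max_size=400), st.integers(0, 3))
def test_digest_conservation_and_palindromy(seq, n_sites):
    """Fragments sum to the sequence length; recognition is strand-symmetric.

    BstEII's site is a palindrome, so the sites found on the reverse
    complement mirror the sites found on the top strand exactly, and all
    interior fragments (between consecutive cuts) are orientation
    independent.  End fragments are measured on a single strand and shift by
    the 5-nt overhang between orientations, so they are compared after
    mirroring the cut positions.
    """
    from kdrmon.assay import iupac_find_all

    rng = np.random.default_rng(len(seq) + n_sites)
    for _ in range(n_sites):  # salt with recognition sites
        i = int(rng.integers(0, len(seq)))
        seq = seq[:i] + "GGTAACC" + seq[i:]
    frags = digest_fragments(seq, BSTEII)
    assert sum(frags) == len(seq)
    rc = reverse_complement(seq)
    assert sum(digest_fragments(rc, BSTEII)) == len(seq)
    sites = iupac_find_all(seq, BSTEII.recognition)
    rc_sites = iupac_find_all(rc, BSTEII.recognition)
    assert sorted(len(seq) - 7 - p for p in rc_sites) == sites
    if len(sites) >= 2:  # interior fragments orientation-independent
        cuts = [p + BSTEII.cut_offset for p in sites]
        interior = [b - a for a, b in zip(cuts, cuts[1:])]
        rc_cuts = sorted(p + BSTEII.cut_offset for p in rc_sites)
        rc_interior = [b - a for a, b in zip(rc_cuts, rc_cuts[1:])]
        assert sorted(interior) == sorted(rc_interior)


# ---------------------------------------------------------------------------
# LCR


@pytest.mark.parametrize(
    "geno, bands, call",
    [(("M", "M"), (141,), "M/M"), (("M", "I"), (141, 165), "M/I"), (("I", "I"), (165,), "I/I")],
)
def test_lcr_band_patterns(reference, geno, bands, call):
    start, end = reference.skdr_amplicon.reference_interval
    base = reference.transcript[start - 1 : end]
    pos = SKDR_LOCUS.transcript_position - start
    allele_seq = {"M": base, "I": base[:pos] + "A" + base[pos + 1 :]}
    alleles = sorted({allele_seq[a] for a in geno})
    res = lcr_genotype(alleles, reference.probes, SKDR_LOCUS)
    assert res.bands == bands
    assert str(res.call) == call


# ---------------------------------------------------------------------------
# direct codon calling


@pytest.mark.parametrize(
    "locus, codon, expected",
    [(SKDR_LOCUS, "ATR", "M/I"), (KDR_LOCUS, "YTT", "L/F"), (KDR_LOCUS, "CTT", "L/L")],
)
def test_call_codon_variant(reference, locus, codon, expected):
    s0 = locus.codon_start - 1
    sample = (
        reference.transcript[:s0] + codon + reference.transcript[s0 + 3 :]
    )
    assert str(call_codon_variant(sample, locus, reference.transcript)) == expected


def test_call_codon_variant_coverage_error(reference):
    with pytest.raises(CoverageError):
        call_codon_variant("ACGT" * 30, KDR_LOCUS, reference.transcript)


# ---------------------------------------------------------------------------
# full-sample genotyping


def test_all_nine_classes_concordant_across_routes(reference):
    cohort = _cohort_of_all_nine()
    seqs = render_sequences(cohort, reference, noise_rate=0.0, seed=0)
    for ind in cohort:
        rep = genotype_sample(seqs[ind.ident], reference)
        assert str(rep.genotype) == ind.ident
        assert rep.genotype.class_label == ind.genotype.class_label
        assert set(rep.methods["L1014F"]) == {"RFLP", "codon"}
        assert set(rep.methods["M918I"]) == {"LCR", "codon"}


def test_rflp_site_corruption_raises_discordance(reference):
    """A lesion inside the recognition site flips the RFLP call only."""
    cohort = _cohort_of_all_nine()
    wt = next(i for i in cohort if i.ident == "L/L:M/M")
    seq = render_sequences([wt], reference, seed=0)[wt.ident]
    site_pos = KDR_LOCUS.transcript_position - 2  # penultimate site base (C)
    corrupted = seq[: site_pos - 1] + "G" + seq[site_pos:]
    with pytest.raises(DiscordanceError) as err:
        genotype_sample(corrupted, reference)
    assert "L1014F" in str(err.value)


def test_ambiguity_at_non_assay_position_never_changes_calls(reference):
    """Monotone ambiguity: an extra IUPAC code off the assay positions is inert."""
    cohort = _cohort_of_all_nine()
    seqs = render_sequences(cohort, reference, seed=0)
    protected = np.zeros(len(reference.transcript), bool)
    for a, b in reference.protected:
        protected[a - 1 : b] = True
    free = np.flatnonzero(~protected)
    rng = np.random.default_rng(7)
    for ind in cohort:
        seq = seqs[ind.ident]
        pos = int(rng.choice(free))
        noisy = seq[:pos] + "N" + seq[pos + 1 :]
        rep = genotype_sample(noisy, reference)
        assert str(rep.genotype) == ind.ident
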