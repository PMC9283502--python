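"""In-silico PCR-RFLP and ligase-chain-reaction (LCR) genotyping.

The kdr (L1014F) assay amplifies a 439 bp fragment spanning the variant and
digests it with BstEII (GGTNACC, cutting G^GTNACC).  The susceptible C allele
retains the recognition site and digests into 154 + 285 bp; the resistant T
allele destroys the site (GGTNACT) and runs undigested at 439 bp;
heterozygotes show all three bands.

The super-kdr (M918I) assay amplifies a 151 bp fragment and runs an LCR in
which an allele-specific upstream probe (3'-terminal G for wild type, A for
mutant) ligates to a common phosphorylated downstream probe only when its
terminal base matches the template.  Tailed amplification of the ligation
products yields 141 bp (wild type) and/or 165 bp (mutant) diagnostics; the
mutant probe carries a 24-base 5' extension so the two products separate on
a gel.

Heterozygous individuals are represented as a single consensus sequence with
IUPAC ambiguity codes (the Sanger "co-occurring peaks" picture), expanded
into concrete allele sequences before each virtual reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import (
    AmbiguityOverflowError,
    AmbiguousPrimingError,
    AmpliconNotFoundError,
    AssayFailureError,
    CoverageError,
    DiscordanceError,
    InvalidSequenceError,
)
from .loci import (
    IUPAC_EXPANSION,
    DiploidCall,
    ResistanceLocus,
    TwoLocusGenotype,
    classify_genotype,
    expand_iupac,
    make_call,
    translate_codon,
)

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise InvalidSequenceError(f"non-IUPAC character {exc.args[0]!r}") from exc


def iupac_match(template: str, pattern: str, pos: int) -> bool:
    """Does ``pattern`` match ``template`` starting at 0-based ``pos``?

    A template IUPAC code matches a pattern code when the expansions
    intersect; a concrete primer base therefore matches a template code only
    if the base is among the code's expansion.
    """
    if pos < 0 or pos + len(pattern) > len(template):
        return False
    for t, p in zip(template[pos : pos + len(pattern)], pattern):
        if not (IUPAC_EXPANSION[t] & IUPAC_EXPANSION[p]):
            return False
    return True


def iupac_find_all(template: str, pattern: str) -> list[int]:
    """0-based start positions of all IUPAC matches of pattern in template."""
    return [
        i
        for i in range(len(template) - len(pattern) + 1)
        if iupac_match(template, pattern, i)
    ]


@dataclass(frozen=True)
class AmpliconSpec:
    """A primer pair and the fragment it amplifies on the reference.

    The reverse primer is given 5'→3' on the opposite strand;
    ``reference_interval`` is 1-based inclusive on the reference transcript.
    """

    name: str
    forward_primer: str
    reverse_primer: str
    expected_length: int
    reference_interval: tuple[int, int]

    def __post_init__(self):
        if self.expected_length <= len(self.forward_primer) + len(self.reverse_primer):
            raise ValueError(
                f"{self.name}: expected_length must exceed the summed primer lengths"
            )

    def validate_against(self, reference: str) -> None:
        """Check both primers occur exactly once and the length matches."""
        amp, start, end = find_amplicon(reference, self)
        if len(amp) != self.expected_length:
            raise ValueError(
                f"{self.name}: reference amplicon is {len(amp)} bp, "
                f"expected {self.expected_length}"
            )
        if (start, end) != self.reference_interval:
            raise ValueError(
                f"{self.name}: amplicon at {start}-{end}, "
                f"expected {self.reference_interval}"
            )


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme with a degenerate palindromic recognition site."""

    name: str = "BstEII"
    recognition: str = "GGTNACC"
    cut_offset: int = 1  # G^GTNACC

    def __post_init__(self):
        if not 0 < self.cut_offset < len(self.recognition):
            raise ValueError("cut_offset must fall inside the recognition site")
        rc = reverse_complement(self.recognition)
        if rc != self.recognition:
            raise ValueError(
                f"{self.name}: recognition {self.recognition} is not palindromic"
            )


@dataclass(frozen=True)
class LCRProbeSet:
    """Allele-specific LCR probes and the product sizes they imply.

    ``p1_wt``/``p1_mut`` are the upstream allele-specific probes whose
    3'-terminal base interrogates the variant; ``p2_phos`` is the common
    5'-phosphorylated downstream probe annealing immediately 3' of the
    variant.  The mutant probe carries a 24-base 5' extension, so the two
    amplified ligation products differ by 24 bp.
    """

    p1_wt: str
    p1_mut: str
    p2_phos: str
    tail_f_len: int = 17
    tail_r_len: int = 18
    wt_product_len: int = 141
    mut_product_len: int = 165

    def __post_init__(self):
        if self.mut_product_len - self.wt_product_len != 24:
            raise ValueError("mutant product must run 24 bp above wild type")
        expect_wt = self.tail_f_len + len(self.p1_wt) + len(self.p2_phos) + self.tail_r_len
        if expect_wt != self.wt_product_len:
            raise ValueError(
                f"wt product {self.wt_product_len} bp inconsistent with "
                f"tails + probes ({expect_wt} bp)"
            )
        if len(self.p1_mut) - len(self.p1_wt) != 24:
            raise ValueError("p1_mut must carry a 24-base 5' extension over p1_wt")


@dataclass(frozen=True)
class AssayResult:
    """Band pattern of a simulated reaction and the diploid call it implies."""

    assay: str  # "RFLP" or "LCR"
    bands: tuple[int, ...]
    call: DiploidCall


def find_amplicon(template: str, spec: AmpliconSpec) -> tuple[str, int, int]:
    """Locate the unique primer-delimited amplicon in a template.

    Returns ``(subsequence, start, end)`` with 1-based inclusive coordinates.
    Primer matching is exact (zero mismatches) but IUPAC-aware on the
    template side; more than one match for either primer raises
    :class:`AmbiguousPrimingError`.
    """
    template = template.upper()
    fwd = iupac_find_all(template, spec.forward_primer.upper())
    rev = iupac_find_all(template, reverse_complement(spec.reverse_primer))
    if not fwd or not rev:
        missing = "forward" if not fwd else "reverse"
        raise AmpliconNotFoundError(
            f"{spec.name}: no {missing}-primer match in template"
        )
    if len(fwd) > 1 or len(rev) > 1:
        raise AmbiguousPrimingError(
            f"{spec.name}: {len(fwd)} forward / {len(rev)} reverse primer matches"
        )
    start = fwd[0]
    end = rev[0] + len(spec.reverse_primer) - 1
    if end <= start:
        raise AmpliconNotFoundError(
            f"{spec.name}: reverse-primer site upstream of forward primer"
        )
    return template[start : end + 1], start + 1, end + 1


def expand_alleles(amplicon: str, max_het_sites: int = 2) -> list[str]:
    """Expand an IUPAC consensus amplicon into concrete allele sequences.

    A consensus with no ambiguity codes expands to itself.  More than
    ``max_het_sites`` ambiguous positions signals an unusable trace and
    raises :class:`AmbiguityOverflowError`.
    """
    amplicon = amplicon.upper()
    n_amb = sum(c not in "ACGT" for c in amplicon)
    for i, c in enumerate(amplicon):
        if c not in IUPAC_EXPANSION:
            raise InvalidSequenceError(f"non-IUPAC character {c!r} at position {i + 1}")
    if n_amb > max_het_sites:
        raise AmbiguityOverflowError(
            f"{n_amb} ambiguous sites exceed the maximum of {max_het_sites}"
        )
    return expand_iupac(amplicon)


def digest_fragments(sequence: str, enzyme: EnzymeSpec) -> list[int]:
    """Fragment lengths from a complete top-strand digest of one sequence."""
    cuts = [p + enzyme.cut_offset for p in iupac_find_all(sequence, enzyme.recognition)]
    bounds = [0] + sorted(cuts) + [len(sequence)]
    return [b - a for a, b in zip(bounds, bounds[1:]) if b > a]


def digest(
    allele_sequences: Sequence[str],
    enzyme: EnzymeSpec,
    locus: ResistanceLocus,
) -> AssayResult:
    """Simulate the PCR-RFLP assay over the expanded alleles of one sample.

    An allele containing the recognition site is scored susceptible (the
    wild-type base retains the site); an allele lacking it is scored
    resistant.  The band pattern is the union of fragment sizes over alleles.
    """
    if not allele_sequences:
        raise AssayFailureError("no template sequences supplied to digest")
    bands: set[int] = set()
    statuses: set[bool] = set()
    for seq in allele_sequences:
        frags = digest_fragments(seq, enzyme)
        bands.update(frags)
        statuses.add(len(frags) > 1)  # True = site present = susceptible allele
    if statuses == {True}:
        call = make_call(locus, [locus.wt_aa])
    elif statuses == {False}:
        call = make_call(locus, [locus.mut_aa])
    else:
        call = make_call(locus, [locus.wt_aa, locus.mut_aa])
    return AssayResult("RFLP", tuple(sorted(bands)), call)


def lcr_genotype(
    allele_sequences: Sequence[str],
    probes: LCRProbeSet,
    locus: ResistanceLocus,
) -> AssayResult:
    """Simulate the allele-specific ligation assay over expanded alleles.

    A P1 probe ligates on an allele iff its annealing region matches with the
    3'-terminal base equal to the allele's variant base and the P2 probe
    anneals immediately downstream.  Wild-type ligation amplifies at
    ``wt_product_len`` (141 bp), mutant at ``mut_product_len`` (165 bp).
    """
    if not allele_sequences:
        raise AssayFailureError("no template sequences supplied to LCR")
    bands: set[int] = set()
    alleles: set[str] = set()
    for seq in allele_sequences:
        seq = seq.upper()
        p2_hits = [p for p in iupac_find_all(seq, probes.p2_phos)]
        for p2 in p2_hits:
            # P1 cores anneal ending immediately 5' of the P2 site.  The
            # mutant probe's 24-base tail does not anneal; only its core
            # (same length as p1_wt) is matched against the template.
            core_len = len(probes.p1_wt)
            start = p2 - core_len
            if start < 0:
                continue
            ext = len(probes.p1_mut) - len(probes.p1_wt)
            if seq[start:p2] == probes.p1_wt:
                bands.add(probes.wt_product_len)
                alleles.add(locus.wt_aa)
            if seq[start:p2] == probes.p1_mut[ext:]:
                bands.add(probes.mut_product_len)
                alleles.add(locus.mut_aa)
    if not alleles:
        raise AssayFailureError("neither LCR probe ligated on any allele")
    return AssayResult("LCR", tuple(sorted(bands)), make_call(locus, alleles))


def call_codon_variant(
    sample_sequence: str,
    locus: ResistanceLocus,
    reference: str,
    flank: int = 20,
) -> DiploidCall:
    """Call a locus directly from an anchored consensus sequence.

    The codon is located by exact match of a ``flank``-bp reference flank
    immediately 5' (falling back to 3') of the codon, then expanded and
    translated: one amino acid → homozygote, two → heterozygote.
    """
    sample = sample_sequence.upper()
    reference = reference.upper()
    start0 = locus.codon_start - 1  # 0-based codon start on the reference
    left = reference[max(0, start0 - flank) : start0]
    right = reference[start0 + 3 : start0 + 3 + flank]
    codon = None
    if len(left) >= flank:
        hits = [i for i in _find_all_exact(sample, left)]
        if len(hits) == 1:
            codon = sample[hits[0] + flank : hits[0] + flank + 3]
    if codon is None and len(right) >= flank:
        hits = [i for i in _find_all_exact(sample, right)]
        if len(hits) == 1 and hits[0] >= 3:
            codon = sample[hits[0] - 3 : hits[0]]
    if codon is None or len(codon) != 3:
        raise CoverageError(
            f"{locus.name}: codon not covered (no unique {flank} bp flank anchor)"
        )
    aas = translate_codon(codon)
    if "*" in aas or len(aas) > 2:
        raise AmbiguityOverflowError(
            f"{locus.name}: codon {codon} translates to {sorted(aas)}"
        )
    return make_call(locus, aas)


def _find_all_exact(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


@dataclass(frozen=True)
class GenotypeReport:
    """A two-locus genotype with per-method provenance."""

    genotype: TwoLocusGenotype
    methods: dict = field(default_factory=dict)  # locus name -> {method: call str}
    bands: dict = field(default_factory=dict)  # assay -> band tuple


def genotype_sample(
    sample_sequence: str,
    reference,
    max_het_sites: int = 2,
) -> GenotypeReport:
    """Genotype one consensus sequence by all three routes and cross-check.

    Runs the BstEII RFLP (1014), the LCR (918) and direct codon calling at
    both loci, then verifies that every route that produced a call agrees.
    ``reference`` is a :class:`kdrmon.simulate.SyntheticReference`-like bundle
    exposing ``transcript``, ``loci``, ``kdr_amplicon``, ``skdr_amplicon``,
    ``enzyme`` and ``probes``.

    Raises :class:`DiscordanceError` listing the conflicting calls when the
    routes disagree (e.g. a corrupted restriction site flips the RFLP call
    but not the codon call).
    """
    loc1014 = reference.loci[1014]
    loc918 = reference.loci[918]

    calls_1014: dict[str, DiploidCall] = {}
    calls_918: dict[str, DiploidCall] = {}
    bands: dict[str, tuple[int, ...]] = {}

    kdr_amp, _, _ = find_amplicon(sample_sequence, reference.kdr_amplicon)
    rflp = digest(expand_alleles(kdr_amp, max_het_sites), reference.enzyme, loc1014)
    calls_1014["RFLP"] = rflp.call
    bands["RFLP"] = rflp.bands

    skdr_amp, _, _ = find_amplicon(sample_sequence, reference.skdr_amplicon)
    lcr = lcr_genotype(expand_alleles(skdr_amp, max_het_sites), reference.probes, loc918)
    calls_918["LCR"] = lcr.call
    bands["LCR"] = lcr.bands

    calls_1014["codon"] = call_codon_variant(sample_sequence, loc1014, reference.transcript)
    calls_918["codon"] = call_codon_variant(sample_sequence, loc918, reference.transcript)

    for locus_name, calls in (("L1014F", calls_1014), ("M918I", calls_918)):
        variants = {str(c) for c in calls.values()}
        if len(variants) > 1:
            listing = ", ".join(f"{m}={c}" for m, c in calls.items())
            raise DiscordanceError(
                f"discordant {locus_name} calls: {listing}",
                calls={locus_name: {m: str(c) for m, c in calls.items()}},
            )

    genotype = classify_genotype(calls_1014["codon"], calls_918["codon"])
    methods = {
        "L1014F": {m: str(c) for m, c in calls_1014.items()},
        "M918I": {m: str(c) for m, c in calls_918.items()},
    }
    return GenotypeReport(genotype=genotype, methods=methods, bands=bands)
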