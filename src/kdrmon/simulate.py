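"""Synthetic vgsc reference, cohorts, field selection and bioassay tables.

Everything the pipeline consumes can be generated here with known ground
truth.  The reference is a deterministic 3525 bp transcript carrying the
wild-type codons CTT (L1014, first base at transcript position 3070) and ATG
(M918, third base at position 2784) in a single reading frame (CDS start 31),
a unique BstEII site whose final C is the 1014 variant base, and unique
primer/probe annealing sites.  The kdr amplicon is 439 bp and the site is
placed so the wild-type digest yields exactly 154 + 285 bp.

Cohorts are drawn as two independent gametes per individual from four
haplotype frequencies (L·M, L·I, F·M, F·I), rendered as Sanger-style
consensus sequences with IUPAC codes at heterozygous positions (Y at 3070,
R at 2784), optionally with uniform substitution noise away from
assay-critical positions.  Field selection is Bernoulli survival per
individual with genotype-class-specific probabilities, and bioassays are
binomial deaths under the LL.3 dose-mortality law.

All randomness flows from one top-level seed through named substreams
(population / noise / selection / bioassay), so stages are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assay import (
    AmpliconSpec,
    EnzymeSpec,
    LCRProbeSet,
    digest_fragments,
    iupac_find_all,
    reverse_complement,
)
from .doseresponse import BioassayRecord, ll3
from .errors import ValidationError
from .loci import (
    DEFAULT_LOCI,
    DiploidCall,
    ResistanceLocus,
    TwoLocusGenotype,
    classify_genotype,
)

_SUBSTREAMS = {"population": 1, "noise": 2, "selection": 3, "bioassay": 4}

#: IUPAC code for each unordered pair of concrete bases.
_PAIR_CODE = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS[name],)))


@dataclass(frozen=True)
class SyntheticReference:
    """A reference transcript plus the assay definitions validated on it."""

    transcript: str
    loci: dict[int, ResistanceLocus]
    kdr_amplicon: AmpliconSpec
    skdr_amplicon: AmpliconSpec
    enzyme: EnzymeSpec
    probes: LCRProbeSet
    protected: tuple[tuple[int, int], ...]  # 1-based inclusive intervals
    seed: int


# fixed layout (1-based transcript coordinates)
_TRANSCRIPT_LEN = 3525
_KDR_AMP = (2911, 3349)      # 439 bp
_SKDR_AMP = (2726, 2876)     # 151 bp
_SITE_START = 3064           # BstEII site 3064..3070; cut after 3064 -> 154+285
_PRIMER_LEN = 20
_P1_CORE_LEN = 25            # p1 core anneals 2760..2784 (3' base = variant)
_P2_LEN = 81                 # p2 anneals 2785..2865; 17+25+81+18 = 141


def make_reference(seed: int = 0) -> SyntheticReference:
    """Deterministically generate the synthetic reference bundle.

    The random backbone is repaired so that the BstEII site is unique within
    the kdr amplicon on both the wild-type and mutant allele, and each
    primer/probe occurs exactly once in the transcript.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=_TRANSCRIPT_LEN))

    def put(pos1: int, s: str):
        for i, ch in enumerate(s):
            seq[pos1 - 1 + i] = ch

    put(2782, "ATG")          # codon 918
    put(_SITE_START, "GGTTACC")  # BstEII site; N fixed to T -> codon 1013 = TAC
    put(3070, "CTT")          # codon 1014 (overwrites site's final C with C,T,T)

    protected = [
        (2782, 2784), (3070, 3072), (_SITE_START, _SITE_START + 6),
        (_KDR_AMP[0], _KDR_AMP[0] + _PRIMER_LEN - 1),
        (_KDR_AMP[1] - _PRIMER_LEN + 1, _KDR_AMP[1]),
        (_SKDR_AMP[0], _SKDR_AMP[0] + _PRIMER_LEN - 1),
        (_SKDR_AMP[1] - _PRIMER_LEN + 1, _SKDR_AMP[1]),
        (2760, 2784), (2785, 2785 + _P2_LEN - 1),
    ]

    # during construction only the codons and the canonical site are
    # immutable; primers and probes are extracted afterwards, so repairs may
    # touch their future footprints
    hard = [(2782, 2784), (3070, 3072), (_SITE_START, _SITE_START + 6)]

    def is_hard(pos1: int) -> bool:
        return any(a <= pos1 <= b for a, b in hard)

    enzyme = EnzymeSpec()

    # repair accidental BstEII matches inside the kdr amplicon, on both the
    # wild-type and the mutant (T at 3070) backbone; the degenerate N
    # position (offset 3) is skipped because flipping it cannot destroy a
    # match
    lo, hi = _KDR_AMP
    for _ in range(200):
        text = "".join(seq)
        mutant = text[:3069] + "T" + text[3070:]
        extra = sorted(
            {
                p
                for t in (text, mutant)
                for p in iupac_find_all(t[lo - 1 : hi], enzyme.recognition)
                if p + lo != _SITE_START
            }
        )
        if not extra:
            break
        pos1 = None
        for off in (0, 1, 2, 4, 5, 6):
            cand = extra[0] + lo + off
            if not is_hard(cand):
                pos1 = cand
                break
        if pos1 is None:  # pragma: no cover - cannot happen: hard spans < 7 apart
            raise ValidationError("cannot repair recognition-site collision")
        seq[pos1 - 1] = {"G": "C", "C": "G", "T": "A", "A": "T"}[seq[pos1 - 1]]
    transcript = "".join(seq)

    def unique_or_repair(sub: str) -> None:
        hits = iupac_find_all(transcript, sub) + iupac_find_all(
            transcript, reverse_complement(sub)
        )
        if len(hits) != 1:  # pragma: no cover - ~0 probability for 20-mers
            raise ValidationError(f"non-unique 20-mer {sub} in synthetic reference")

    kdr_fwd = transcript[_KDR_AMP[0] - 1 : _KDR_AMP[0] - 1 + _PRIMER_LEN]
    kdr_rev = reverse_complement(transcript[_KDR_AMP[1] - _PRIMER_LEN : _KDR_AMP[1]])
    skdr_fwd = transcript[_SKDR_AMP[0] - 1 : _SKDR_AMP[0] - 1 + _PRIMER_LEN]
    skdr_rev = reverse_complement(transcript[_SKDR_AMP[1] - _PRIMER_LEN : _SKDR_AMP[1]])
    for p in (kdr_fwd, kdr_rev, skdr_fwd, skdr_rev):
        unique_or_repair(p)

    kdr_amplicon = AmpliconSpec(
        name="AGkdr", forward_primer=kdr_fwd, reverse_primer=kdr_rev,
        expected_length=_KDR_AMP[1] - _KDR_AMP[0] + 1, reference_interval=_KDR_AMP,
    )
    skdr_amplicon = AmpliconSpec(
        name="AGskdr", forward_primer=skdr_fwd, reverse_primer=skdr_rev,
        expected_length=_SKDR_AMP[1] - _SKDR_AMP[0] + 1, reference_interval=_SKDR_AMP,
    )
    p1_wt = transcript[2784 - _P1_CORE_LEN : 2784]      # ends with G at 2784
    p1_mut = ("TGACGTCAGGCATCTAGAGCTTGCA" [:24]) + p1_wt[:-1] + "A"
    p2 = transcript[2785 - 1 : 2785 - 1 + _P2_LEN]
    probes = LCRProbeSet(p1_wt=p1_wt, p1_mut=p1_mut, p2_phos=p2)

    ref = SyntheticReference(
        transcript=transcript,
        loci=dict(DEFAULT_LOCI),
        kdr_amplicon=kdr_amplicon,
        skdr_amplicon=skdr_amplicon,
        enzyme=enzyme,
        probes=probes,
        protected=tuple(protected),
        seed=seed,
    )
    _validate_reference(ref)
    return ref


def _validate_reference(ref: SyntheticReference) -> None:
    ref.kdr_amplicon.validate_against(ref.transcript)
    ref.skdr_amplicon.validate_against(ref.transcript)
    amp_start, amp_end = ref.kdr_amplicon.reference_interval
    amplicon = ref.transcript[amp_start - 1 : amp_end]
    frags = digest_fragments(amplicon, ref.enzyme)
    if sorted(frags) != [154, 285]:
        raise ValidationError(f"wild-type digest gives {sorted(frags)}, expected [154, 285]")
    if ref.transcript[3069:3072] != "CTT" or ref.transcript[2781:2784] != "ATG":
        raise ValidationError("wild-type codons corrupted")


# ---------------------------------------------------------------------------
# populations


HAPLOTYPES = ("LM", "LI", "FM", "FI")  # allele at 1014 then at 918


@dataclass(frozen=True)
class HaplotypeFrequencies:
    """Frequencies of the four two-locus haplotypes, summing to 1."""

    lm: float
    li: float
    fm: float
    fi: float

    def __post_init__(self):
        vec = self.as_array()
        if (vec < 0).any() or (vec > 1).any():
            raise ValidationError("haplotype frequencies must lie in [0, 1]")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValidationError(f"haplotype frequencies sum to {vec.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.lm, self.li, self.fm, self.fi], dtype=float)

    @property
    def p_f(self) -> float:
        """Implied frequency of the 1014F allele."""
        return self.fm + self.fi

    @property
    def p_i(self) -> float:
        """Implied frequency of the 918I allele."""
        return self.li + self.fi


#: default field-like condition: mostly kdr-bearing haplotypes with a
#: minority super-kdr haplotype, mirroring the pre-application spectrum
#: (1014F RAF 0.40, 918I RAF 0.10) seen in pooled monitoring counts.
DEFAULT_FREQS = HaplotypeFrequencies(lm=0.58, li=0.02, fm=0.32, fi=0.08)


@dataclass(frozen=True)
class Individual:
    """A diploid individual with ground-truth haplotypes and genotype."""

    ident: str
    haplotypes: tuple[str, str]
    genotype: TwoLocusGenotype


def _genotype_from_haplotypes(h1: str, h2: str) -> TwoLocusGenotype:
    call_1014 = DiploidCall(DEFAULT_LOCI[1014], (h1[0], h2[0]))
    call_918 = DiploidCall(DEFAULT_LOCI[918], (h1[1], h2[1]))
    return classify_genotype(call_1014, call_918)


def sample_population(
    freqs: HaplotypeFrequencies, n: int, seed: int = 0
) -> list[Individual]:
    """Draw n individuals as random unions of two independent gametes."""
    rng = _stream(seed, "population")
    draws = rng.choice(len(HAPLOTYPES), size=(n, 2), p=freqs.as_array())
    out = []
    for i, (a, b) in enumerate(draws):
        h1, h2 = HAPLOTYPES[a], HAPLOTYPES[b]
        out.append(
            Individual(f"ind{i:05d}", (h1, h2), _genotype_from_haplotypes(h1, h2))
        )
    return out


def render_sequences(
    individuals: Sequence[Individual],
    reference: SyntheticReference,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, str]:
    """Per-individual IUPAC consensus transcripts (Sanger-style).

    Heterozygous sites appear as ambiguity codes (Y at 3070, R at 2784).
    ``noise_rate`` applies uniform substitutions per base away from the
    assay-critical (protected) positions, modelling trace errors shared by
    both strands of the consensus.
    """
    rng = _stream(seed, "noise")
    base = reference.transcript
    loc1014 = reference.loci[1014]
    loc918 = reference.loci[918]
    allele_base = {
        1014: {"L": loc1014.wt_base, "F": loc1014.mut_base},
        918: {"M": loc918.wt_base, "I": loc918.mut_base},
    }
    protected_mask = np.zeros(len(base), dtype=bool)
    for a, b in reference.protected:
        protected_mask[a - 1 : b] = True
    free_positions = np.flatnonzero(~protected_mask)

    out: dict[str, str] = {}
    for ind in individuals:
        seq = list(base)
        for pos_aa, pos_nt in ((1014, loc1014.transcript_position), (918, loc918.transcript_position)):
            pair = frozenset(
                allele_base[pos_aa][h[0 if pos_aa == 1014 else 1]]
                for h in ind.haplotypes
            )
            seq[pos_nt - 1] = _PAIR_CODE[pair]
        if noise_rate > 0 and len(free_positions):
            hits = free_positions[rng.random(len(free_positions)) < noise_rate]
            for p in hits:
                current = seq[p]
                choices = [b for b in "ACGT" if b != current]
                seq[p] = choices[rng.integers(3)]
        out[ind.ident] = "".join(seq)
    return out


# ---------------------------------------------------------------------------
# selection and bioassays


@dataclass(frozen=True)
class SelectionModel:
    """Per-genotype-class survival probabilities for a field application."""

    survival: dict

    def __post_init__(self):
        for cls, p in self.survival.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"survival for {cls!r} outside [0, 1]")

    def prob(self, genotype: TwoLocusGenotype) -> float:
        if genotype.class_label in self.survival:
            return self.survival[genotype.class_label]
        return self.survival.get("default", 0.0)


#: survival ordered with resistance: wild type lowest, super-kdr highest.
DEFAULT_SELECTION = SelectionModel(
    survival={
        "wild type": 0.05,
        "918-only": 0.05,
        "kdr heterozygote": 0.40,
        "kdr homozygote": 0.60,
        "super-kdr heterozygote": 0.80,
        "super-kdr homozygote": 0.90,
    }
)


def apply_selection(
    individuals: Sequence[Individual], model: SelectionModel, seed: int = 0
) -> tuple[list[Individual], list[Individual]]:
    """Split a cohort into (survivors, moribund) by Bernoulli survival."""
    rng = _stream(seed, "selection")
    u = rng.random(len(individuals))
    survivors, moribund = [], []
    for ind, ui in zip(individuals, u):
        (survivors if ui < model.prob(ind.genotype) else moribund).append(ind)
    return survivors, moribund


def simulate_bioassay(
    b: float,
    d: float,
    e: float,
    doses: Sequence[float],
    n_per_dose: int,
    seed: int = 0,
    population: str = "synthetic",
    treatment: str = "lambda-cyhalothrin",
    include_control: bool = True,
) -> list[BioassayRecord]:
    """Binomial dose-mortality records under the LL.3 law.

    Defaults mirror the monitoring design: 7-8 concentrations spanning the
    response, 3 x 20 aphids per dose pooled to 60.  Dose-0 control rows draw
    deaths at a 1% background rate.
    """
    rng = _stream(seed, "bioassay")
    records = []
    if include_control:
        dead = int(rng.binomial(n_per_dose, 0.01))
        records.append(BioassayRecord(population, treatment, 0.0, n_per_dose, dead))
    for x in doses:
        p = float(ll3(x, b, d, e))
        dead = int(rng.binomial(n_per_dose, p))
        records.append(BioassayRecord(population, treatment, float(x), n_per_dose, dead))
    return records


def design_doses(e: float, n_doses: int = 8, span: float = 8.0) -> tuple[float, ...]:
    """A geometric dose grid bracketing a population's LC50.

    Bioassay practice spaces the treatment concentrations so that the
    response runs from near-zero to near-complete mortality; a grid from
    e/span to e*span (default 8-fold either side) achieves that for slopes
    around 2-3.  The grid is clipped to the assay envelope 0.0008-60 ug/ml.
    """
    lo = max(e / span, 0.0008)
    hi = min(e * span, 60.0)
    return tuple(float(x) for x in np.geomspace(lo, hi, n_doses))


#: the monitoring bioassay dose grid (ug/ml) for the susceptible-reference
#: condition (LC50 0.38): 8 concentrations bracketing the LC50 inside the
#: assay envelope 0.0008-60.
DEFAULT_DOSES = design_doses(0.38)
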