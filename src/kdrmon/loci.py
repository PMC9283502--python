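"""Resistance loci, codon translation and two-locus genotype classification.

The surveillance targets are two voltage-gated sodium channel (vgsc) codons,
named in Musca-orthologous numbering: L1014F (kdr, CTT→TTT) and M918I
(super-kdr partner, ATG→ATA).  A diploid individual is summarised by one
amino-acid call per locus and a resistance-class label derived from the pair:

=========  =========  ======================
1014       918        class
=========  =========  ======================
L/L        M/M        wild type
L/F        M/M        kdr heterozygote
F/F        M/M        kdr homozygote
any F      any I      super-kdr heterozygote
F/F        I/I        super-kdr homozygote
L/L        any I      918-only
=========  =========  ======================

Heterozygous positions in Sanger consensus sequences are represented with
IUPAC ambiguity codes (Y = C/T at 1014, R = G/A at 918), so codon translation
must expand ambiguity codes before applying the genetic code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product
from typing import Iterable

import yaml
from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_values

from .errors import GenotypeParseError, InvalidSequenceError, LocusMismatchError

#: the 15 IUPAC nucleotide codes (4 concrete + 11 ambiguous).
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

#: expansion of each IUPAC code into concrete bases.
IUPAC_EXPANSION = {c: frozenset(ambiguous_dna_values[c]) for c in IUPAC_CODES}

_CODON_TABLE = dict(standard_dna_table.forward_table)
_CODON_TABLE.update({c: "*" for c in standard_dna_table.stop_codons})


def expand_iupac(seq: str) -> list[str]:
    """All concrete sequences consistent with an IUPAC-coded sequence."""
    pools = []
    for i, ch in enumerate(seq.upper()):
        if ch not in IUPAC_EXPANSION:
            raise InvalidSequenceError(
                f"non-IUPAC character {ch!r} at position {i + 1}"
            )
        pools.append(sorted(IUPAC_EXPANSION[ch]))
    return ["".join(p) for p in product(*pools)]


def translate_codon(codon: str) -> frozenset[str]:
    """Translate a 3-mer, expanding IUPAC ambiguity codes.

    Returns the set of amino acids (single letters, ``*`` for stop) obtained
    by translating every concrete expansion of the codon with the standard
    genetic code.  ``"CTT"`` → ``{"L"}``; ``"YTT"`` → ``{"L", "F"}``.
    """
    if len(codon) != 3:
        raise InvalidSequenceError(f"codon must have length 3, got {codon!r}")
    return frozenset(_CODON_TABLE[c] for c in expand_iupac(codon))


@dataclass(frozen=True)
class ResistanceLocus:
    """A codon position under resistance surveillance.

    Parameters
    ----------
    name:
        Field label, e.g. ``"L1014F"``.
    aa_position:
        Amino-acid position in Musca-orthologous numbering (1014, 918).
    transcript_position:
        1-based coordinate of the variant nucleotide on the reference
        transcript (3070 for L1014F, 2784 for M918I).
    codon_offset:
        Position of the variant base within the codon, in {1, 2, 3}.
    wt_codon, mut_codon:
        Concrete 3-mers differing at exactly ``codon_offset``.
    wt_aa, mut_aa:
        Single-letter translations of the two codons.
    """

    name: str
    aa_position: int
    transcript_position: int
    codon_offset: int
    wt_codon: str
    mut_codon: str
    wt_aa: str
    mut_aa: str

    def __post_init__(self):
        if self.codon_offset not in (1, 2, 3):
            raise ValueError(f"codon_offset must be 1..3, got {self.codon_offset}")
        diffs = [i for i in range(3) if self.wt_codon[i] != self.mut_codon[i]]
        if diffs != [self.codon_offset - 1]:
            raise ValueError(
                f"{self.name}: codons {self.wt_codon}/{self.mut_codon} must "
                f"differ exactly at offset {self.codon_offset}"
            )
        if translate_codon(self.wt_codon) != {self.wt_aa}:
            raise ValueError(f"{self.name}: {self.wt_codon} does not encode {self.wt_aa}")
        if translate_codon(self.mut_codon) != {self.mut_aa}:
            raise ValueError(f"{self.name}: {self.mut_codon} does not encode {self.mut_aa}")

    @property
    def codon_start(self) -> int:
        """1-based transcript coordinate of the codon's first base."""
        return self.transcript_position - (self.codon_offset - 1)

    @property
    def wt_base(self) -> str:
        return self.wt_codon[self.codon_offset - 1]

    @property
    def mut_base(self) -> str:
        return self.mut_codon[self.codon_offset - 1]


#: canonical locus definitions (vgsc-h1 transcript coordinates).
KDR_LOCUS = ResistanceLocus(
    name="L1014F", aa_position=1014, transcript_position=3070, codon_offset=1,
    wt_codon="CTT", mut_codon="TTT", wt_aa="L", mut_aa="F",
)
SKDR_LOCUS = ResistanceLocus(
    name="M918I", aa_position=918, transcript_position=2784, codon_offset=3,
    wt_codon="ATG", mut_codon="ATA", wt_aa="M", mut_aa="I",
)
DEFAULT_LOCI = {1014: KDR_LOCUS, 918: SKDR_LOCUS}


def loci_from_config(path) -> dict[int, ResistanceLocus]:
    """Load locus definitions from a small YAML config.

    Each entry gives name, aa_position, transcript_position, codon_offset and
    the wild-type/mutant codons; amino acids are derived by translation.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    loci = {}
    for entry in raw["loci"]:
        wt_aa = next(iter(translate_codon(entry["wt_codon"])))
        mut_aa = next(iter(translate_codon(entry["mut_codon"])))
        loc = ResistanceLocus(
            name=entry["name"],
            aa_position=int(entry["aa_position"]),
            transcript_position=int(entry["transcript_position"]),
            codon_offset=int(entry["codon_offset"]),
            wt_codon=entry["wt_codon"].upper(),
            mut_codon=entry["mut_codon"].upper(),
            wt_aa=wt_aa,
            mut_aa=mut_aa,
        )
        loci[loc.aa_position] = loc
    return loci


@dataclass(frozen=True)
class DiploidCall:
    """An unordered pair of amino-acid alleles at one locus.

    Rendered canonically wild-type-first ("L/F", never "F/L").
    """

    locus: ResistanceLocus
    alleles: tuple[str, str]

    def __post_init__(self):
        valid = {self.locus.wt_aa, self.locus.mut_aa, "?"}
        for a in self.alleles:
            if a not in valid:
                raise ValueError(f"allele {a!r} not valid for locus {self.locus.name}")
        object.__setattr__(self, "alleles", self._canonical(self.alleles))

    def _canonical(self, alleles):
        order = {self.locus.wt_aa: 0, self.locus.mut_aa: 1, "?": 2}
        return tuple(sorted(alleles, key=order.__getitem__))

    @property
    def zygosity(self) -> str:
        a, b = self.alleles
        if "?" in self.alleles:
            return "unknown"
        if a == b:
            return "hom-wt" if a == self.locus.wt_aa else "hom-mut"
        return "het"

    @property
    def n_mut(self) -> int:
        """Number of mutant alleles carried (0, 1 or 2)."""
        return sum(a == self.locus.mut_aa for a in self.alleles)

    def __str__(self) -> str:
        return "/".join(self.alleles)


def make_call(locus: ResistanceLocus, aa_set: Iterable[str]) -> DiploidCall:
    """Diploid call from the amino acids seen in a consensus codon.

    One amino acid → homozygous; two → heterozygous.
    """
    aas = sorted(set(aa_set))
    if len(aas) == 1:
        return DiploidCall(locus, (aas[0], aas[0]))
    if len(aas) == 2:
        return DiploidCall(locus, (aas[0], aas[1]))
    raise ValueError(f"cannot form a diploid call from {aas}")


CLASS_LABELS = (
    "wild type",
    "kdr heterozygote",
    "kdr homozygote",
    "super-kdr heterozygote",
    "super-kdr homozygote",
    "918-only",
)

#: the nine concrete two-locus genotype strings, in report column order
#: (1014 outer, 918 inner).
NINE_CLASSES = (
    "L/L:M/M", "L/L:M/I", "L/L:I/I",
    "L/F:M/M", "L/F:M/I", "L/F:I/I",
    "F/F:M/M", "F/F:M/I", "F/F:I/I",
)


@dataclass(frozen=True)
class TwoLocusGenotype:
    """Joint diploid genotype at the 1014 and 918 loci."""

    call_1014: DiploidCall
    call_918: DiploidCall
    class_label: str

    def __str__(self) -> str:
        return f"{self.call_1014}:{self.call_918}"

    @property
    def nine_class(self) -> str:
        return str(self)


def classify_genotype(call_1014: DiploidCall, call_918: DiploidCall) -> TwoLocusGenotype:
    """Assign the kdr/super-kdr resistance class to a pair of diploid calls.

    Any 1014F allele together with any 918I allele makes a super-kdr
    heterozygote unless both loci are homozygous mutant (super-kdr
    homozygote).  918I without 1014F is kept out of the kdr/super-kdr
    classes and labelled "918-only".
    """
    if call_1014.locus.aa_position != 1014:
        raise LocusMismatchError(
            f"first call is for locus {call_1014.locus.aa_position}, expected 1014"
        )
    if call_918.locus.aa_position != 918:
        raise LocusMismatchError(
            f"second call is for locus {call_918.locus.aa_position}, expected 918"
        )
    f = call_1014.n_mut
    i = call_918.n_mut
    if f == 0:
        label = "wild type" if i == 0 else "918-only"
    elif i == 0:
        label = "kdr heterozygote" if f == 1 else "kdr homozygote"
    elif f == 2 and i == 2:
        label = "super-kdr homozygote"
    else:
        label = "super-kdr heterozygote"
    return TwoLocusGenotype(call_1014, call_918, label)


_GENOTYPE_RE = re.compile(r"^([LF])/([LF]):([MI])/([MI])$")


def parse_genotype_string(
    text: str,
    locus_1014: ResistanceLocus = KDR_LOCUS,
    locus_918: ResistanceLocus = SKDR_LOCUS,
) -> TwoLocusGenotype:
    """Parse a nine-class genotype string such as ``"L/F:M/I"``.

    Allele order within a locus is canonicalised wild-type-first, so
    ``"F/L:M/M"`` parses to the same genotype as ``"L/F:M/M"``.
    """
    m = _GENOTYPE_RE.match(text.strip())
    if not m:
        raise GenotypeParseError(f"not a genotype string: {text!r}")
    a, b, c, d = m.groups()
    return classify_genotype(
        DiploidCall(locus_1014, (a, b)), DiploidCall(locus_918, (c, d))
    )
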