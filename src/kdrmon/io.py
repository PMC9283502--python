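"""File formats, packaged count-table fixtures and the two experiment runners.

All tabular I/O is TSV (tab-separated, header row, UTF-8, "." decimal).
FASTA goes through Biopython and preserves the IUPAC alphabet verbatim.
Rounding happens only at the report layer; internal computation keeps full
precision.

Two report bundles mirror the monitoring study's designs:

* experiment 1 — genotype vs survivor/moribund association: per-stratum
  nine-class percentages and an exact 2 x k test p-value;
* experiment 2 — pre/post application allele trend: per-location RAF and
  allele-count odds ratios plus the equal-weight pooled OR from the
  interaction logit model.
"""

from __future__ import annotations

import io as _io
import json
import sys
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DegenerateTableError, InvalidSequenceError, ValidationError
from .loci import IUPAC_CODES, NINE_CLASSES
from .stats import (
    GenotypeCountTable,
    allele_or,
    fisher_exact_2xk,
    fit_allele_glm,
    model_raf,
    pooled_or,
    raf,
)

_NINE_COLS = [cls.replace("/", "").replace(":", "") for cls in NINE_CLASSES]
_LOCUS_COLS = ["LL", "LF", "FF", "MM", "MI", "II"]


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an id → sequence dict, validating the IUPAC alphabet."""
    seqs: dict[str, str] = {}
    with open(path, newline=None) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        import warnings

        warnings.warn(f"{path}: empty FASTA", stacklevel=2)
    for rec in records:
        if rec.id in seqs:
            raise ValidationError(f"{path}: duplicate identifier {rec.id!r}")
        s = str(rec.seq).upper()
        for i, ch in enumerate(s):
            if ch not in IUPAC_CODES:
                raise InvalidSequenceError(
                    f"{path}:{rec.id}: non-IUPAC character {ch!r} at position {i + 1}"
                )
        seqs[rec.id] = s
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_genotype_table(path) -> list[GenotypeCountTable]:
    """Read a nine-class (association-experiment) count table from TSV.

    Columns: location, year, insecticide, group, n, then the nine genotype
    columns LLMM ... FFII in report order.
    """
    df = pd.read_csv(path, sep="\t")
    _require(df, ["location", "year", "insecticide", "group", "n"] + _NINE_COLS, path)
    tables = []
    for idx, row in df.iterrows():
        counts = {
            cls: int(row[col]) for cls, col in zip(NINE_CLASSES, _NINE_COLS)
        }
        try:
            tables.append(
                GenotypeCountTable(
                    location=str(row["location"]), year=int(row["year"]),
                    group=str(row["group"]), n=int(row["n"]), counts=counts,
                    insecticide=str(row["insecticide"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx + 2}: {exc}") from exc
    return tables


def read_locus_table(path) -> list[GenotypeCountTable]:
    """Read a per-locus-margin (allele-trend experiment) count table from TSV.

    Columns: location, year, group, n, LL, LF, FF, MM, MI, II.
    """
    df = pd.read_csv(path, sep="\t")
    _require(df, ["location", "year", "group", "n"] + _LOCUS_COLS, path)
    tables = []
    for idx, row in df.iterrows():
        try:
            tables.append(
                GenotypeCountTable(
                    location=str(row["location"]), year=int(row["year"]),
                    group=str(row["group"]), n=int(row["n"]),
                    margins={
                        1014: (int(row["LL"]), int(row["LF"]), int(row["FF"])),
                        918: (int(row["MM"]), int(row["MI"]), int(row["II"])),
                    },
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx + 2}: {exc}") from exc
    return tables


def read_bioassay_table(path):
    """Read bioassay records (population, treatment, dose, n, dead) from TSV."""
    from .doseresponse import BioassayRecord

    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    _require(df, ["population", "treatment", "dose", "n", "dead"], path)
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                BioassayRecord(
                    population=str(row["population"]), treatment=str(row["treatment"]),
                    dose=float(row["dose"]), n_exposed=int(row["n"]), n_dead=int(row["dead"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx + 2}: {exc}") from exc
    return records


def write_bioassay_table(records, path, seed=None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("population\ttreatment\tdose\tn\tdead\n")
        for r in records:
            fh.write(f"{r.population}\t{r.treatment}\t{r.dose!r}\t{r.n_exposed}\t{r.n_dead}\n")


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def load_association_fixture() -> list[GenotypeCountTable]:
    """The packaged survivor/moribund genotype counts (association experiment)."""
    with resources.as_file(
        resources.files("kdrmon.data") / "association_counts.tsv"
    ) as p:
        return read_genotype_table(p)


def load_trend_fixture() -> list[GenotypeCountTable]:
    """The packaged pre/post-application locus-margin counts (trend experiment)."""
    with resources.as_file(resources.files("kdrmon.data") / "trend_counts.tsv") as p:
        return read_locus_table(p)


# ---------------------------------------------------------------------------
# experiment runners


def association_report(tables: list[GenotypeCountTable]) -> pd.DataFrame:
    """Experiment 1: per-stratum genotype percentages and exact-test p.

    Strata are (year, insecticide, location); each needs a moribund and a
    survivor table.  A stratum with an empty group gets a missing p-value.
    """
    rows = []
    keyed: dict[tuple, dict[str, GenotypeCountTable]] = {}
    for t in tables:
        keyed.setdefault((t.year, t.insecticide, t.location), {})[t.group] = t
    for (year, insecticide, location), groups in keyed.items():
        if set(groups) != {"moribund", "survivor"}:
            raise ValidationError(
                f"{location} {year} {insecticide}: need moribund and survivor groups"
            )
        mor, sur = groups["moribund"], groups["survivor"]
        try:
            p = fisher_exact_2xk([mor.nine_class_vector(), sur.nine_class_vector()])
        except DegenerateTableError:
            p = float("nan")
        for t in (mor, sur):
            row = {
                "year": year, "insecticide": insecticide, "location": location,
                "group": t.group, "n": t.n,
            }
            for cls, col in zip(NINE_CLASSES, _NINE_COLS):
                cnt = (t.counts or {}).get(cls, 0)
                row[col] = cnt
                row[f"{col}_pct"] = round(100.0 * cnt / t.n, 1) if t.n else float("nan")
            row["p_value"] = round(p, 3) if p == p else float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


def trend_report(tables: list[GenotypeCountTable]) -> pd.DataFrame:
    """Experiment 2: RAF and odds-ratio analysis of pre/post samples.

    Per (year, locus): one row per location with pre/post RAF and the raw
    allele-count OR, plus an all-locations row carrying the pooled RAFs and
    the equal-weight model-pooled OR.  Pooled rows in the input (location
    'All') contribute the raw pooled RAFs.
    """
    rows = []
    years = sorted({t.year for t in tables})
    for year in years:
        yr = [t for t in tables if t.year == year]
        locations = sorted({t.location for t in yr if t.location != "All"})
        for aa in (1014, 918):
            strata = []
            for loc in locations:
                pre = _one(yr, loc, "pre")
                post = _one(yr, loc, "post")
                o = allele_or(pre.allele_count(aa), post.allele_count(aa))
                rows.append(
                    {"year": year, "locus": aa, "location": loc,
                     "n_pre": pre.n, "n_post": post.n,
                     "raf_pre": round(raf(pre, aa), 1),
                     "raf_post": round(raf(post, aa), 1),
                     "odds_ratio": round(o.estimate, 2),
                     "or_ci_low": round(o.ci[0], 2), "or_ci_high": round(o.ci[1], 2),
                     "p_value": round(o.p, 4), "pooling": o.pooling,
                     "corrected": o.corrected}
                )
                strata.append((loc, pre.allele_count(aa), post.allele_count(aa)))
            fit = fit_allele_glm(strata)
            pooled = pooled_or(fit)
            pre_all = _one(yr, "All", "pre", optional=True)
            post_all = _one(yr, "All", "post", optional=True)
            m_pre, _ = model_raf(fit, "pre")
            m_post, _ = model_raf(fit, "post")
            rows.append(
                {"year": year, "locus": aa, "location": "All",
                 "n_pre": pre_all.n if pre_all else sum(s[1].n_res + s[1].n_sus for s in strata) // 2,
                 "n_post": post_all.n if post_all else sum(s[2].n_res + s[2].n_sus for s in strata) // 2,
                 "raf_pre": round(raf(pre_all, aa), 1) if pre_all else round(m_pre, 1),
                 "raf_post": round(raf(post_all, aa), 1) if post_all else round(m_post, 1),
                 "odds_ratio": round(pooled.estimate, 2),
                 "or_ci_low": round(pooled.ci[0], 2), "or_ci_high": round(pooled.ci[1], 2),
                 "p_value": round(pooled.p, 4), "pooling": pooled.pooling,
                 "corrected": pooled.corrected}
            )
    return pd.DataFrame(rows)


def _one(tables, location, group, optional=False):
    hits = [t for t in tables if t.location == location and t.group == group]
    if len(hits) == 1:
        return hits[0]
    if optional and not hits:
        return None
    raise ValidationError(f"expected one table for {location}/{group}, found {len(hits)}")


@dataclass
class RunConfig:
    """Paths, switches and reporting options for a full experiment run."""

    association_table: Path | None = None
    trend_table: Path | None = None
    output_dir: Path = Path("kdrmon_out")
    seed: int = 0

    def validate(self) -> None:
        for p in (self.association_table, self.trend_table):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")


def run_experiment(config: RunConfig, log=sys.stderr) -> dict[str, pd.DataFrame]:
    """Run both monitoring experiments and write TSV + summary reports.

    Uses the packaged fixtures for any table not supplied.  Reports are
    byte-identical across repeated runs with the same config and seed, and
    every numeric cell is reproducible from the raw counts alone.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    assoc_tables = (
        read_genotype_table(config.association_table)
        if config.association_table
        else load_association_fixture()
    )
    trend_tables = (
        read_locus_table(config.trend_table)
        if config.trend_table
        else load_trend_fixture()
    )

    assoc = association_report(assoc_tables)
    trend = trend_report(trend_tables)
    assoc.to_csv(out / "association_report.tsv", sep="\t", index=False)
    trend.to_csv(out / "trend_report.tsv", sep="\t", index=False)

    summary = _io.StringIO()
    summary.write(f"kdrmon run (seed={config.seed})\n")
    summary.write(f"association strata: {len(assoc) // 2}\n")
    for _, r in trend[trend["location"] == "All"].iterrows():
        summary.write(
            f"{int(r['year'])} locus {int(r['locus'])}: pooled OR "
            f"{r['odds_ratio']:.2f} (RAF {r['raf_pre']:.1f} -> {r['raf_post']:.1f}), "
            f"p={r['p_value']:.4f}\n"
        )
    (out / "summary.txt").write_text(summary.getvalue())
    (out / "run_log.json").write_text(
        json.dumps({"seed": config.seed,
                    "association_rows": len(assoc), "trend_rows": len(trend)},
                   indent=2)
    )
    print(summary.getvalue(), end="", file=log)
    return {"association": assoc, "trend": trend}
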