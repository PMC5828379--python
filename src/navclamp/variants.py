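"""Rare-variant triage and carrier association for a case/control cohort.

Implements the screening rule used for SCN9A missense variants in the
painful vs painless diabetic-neuropathy cohort: a variant is set aside as
unlikely pathogenic only when it is BOTH common (minor allele frequency
above 1% in population databases) AND not previously reported in the
literature in association with painful neuropathy — so a literature report
overrides a high frequency.  Pathogenicity consensus counts calls from the
four standard predictors (Align-GVGD, SIFT, MutationTaster, PolyPhen-2);
the carrier association compares participant-level carrier counts between
groups with Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PREDICTORS",
    "VariantRecord",
    "CarrierTable",
    "FilterResult",
    "filter_rare",
    "consensus_pathogenicity",
    "count_carriers",
    "carrier_association",
    "read_variants_tsv",
    "write_variants_tsv",
    "read_variants_vcf",
]

PREDICTORS = ("AlignGVGD", "SIFT", "MutationTaster", "PolyPhen2")
_CALLS = ("pathogenic", "benign", "unknown")


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant.

    ``maf`` maps database name to allele frequency (a database the variant
    was not observed in is simply absent).  ``predictions`` maps predictor
    name to 'pathogenic' / 'benign' / 'unknown'.
    """

    variant_id: str
    protein_change: str = ""
    maf: dict = field(default_factory=dict)
    literature_pain_flag: bool = False
    predictions: dict = field(default_factory=dict)
    carrier_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for db, f in self.maf.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"MAF {f} for {db} outside [0, 1]")
        for alg, call in self.predictions.items():
            if alg not in PREDICTORS:
                raise ValueError(f"unknown predictor {alg!r}")
            if call not in _CALLS:
                raise ValueError(f"unknown prediction {call!r}")


@dataclass(frozen=True)
class CarrierTable:
    """2x2 carrier-by-group counts (a,b = group 1; c,d = group 2)."""

    a: int  # carriers, group 1
    b: int  # non-carriers, group 1
    c: int  # carriers, group 2
    d: int  # non-carriers, group 2
    group1: str = "painful"
    group2: str = "painless"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class FilterResult:
    kept: list
    excluded: list  # (VariantRecord, reason_code) pairs


def _is_common(v: VariantRecord, maf_threshold: float, db_mode: str) -> bool:
    observed = [f for f in v.maf.values() if not (f is None or np.isnan(f))]
    if not observed:
        return False
    if db_mode == "all":
        return all(f > maf_threshold for f in observed)
    if db_mode == "any":
        return any(f > maf_threshold for f in observed)
    raise ValueError(f"unknown db_mode {db_mode!r}")


def filter_rare(
    variants, maf_threshold: float = 0.01, db_mode: str = "all"
) -> FilterResult:
    """Apply the rare-variant triage rule, order-preserving.

    A variant is excluded only if it is common (MAF above threshold — in
    every database where observed for ``db_mode='all'``, in any for
    ``'any'``) AND carries no literature pain association.  Excluded
    variants are returned with the reason code ``common_no_literature``.
    """
    kept, excluded = [], []
    for v in variants:
        if _is_common(v, maf_threshold, db_mode) and not v.literature_pain_flag:
            excluded.append((v, "common_no_literature"))
        else:
            kept.append(v)
    return FilterResult(kept=kept, excluded=excluded)


def consensus_pathogenicity(v: VariantRecord) -> dict:
    """Count pathogenic calls across the four predictors.

    Missing or 'unknown' calls count as not pathogenic.  Returns
    ``{"n_pathogenic": 0..4, "unanimous": bool}``; unanimous means all four
    predictors called pathogenic.
    """
    n = sum(1 for alg in PREDICTORS if v.predictions.get(alg) == "pathogenic")
    return {"n_pathogenic": n, "unanimous": n == len(PREDICTORS)}


def count_carriers(
    variants, group_assignments: dict, group1: str = "painful", group2: str = "painless"
) -> CarrierTable:
    """Participant-level carrier counts per group.

    A participant carrying one or more of the given variants counts once,
    regardless of how many variants it carries.
    """
    carriers: set[str] = set()
    for v in variants:
        carriers.update(v.carrier_ids)
    unknown = carriers - set(group_assignments)
    if unknown:
        raise KeyError(f"carriers with no group assignment: {sorted(unknown)}")
    n1 = sum(1 for g in group_assignments.values() if g == group1)
    n2 = sum(1 for g in group_assignments.values() if g == group2)
    a = sum(1 for pid in carriers if group_assignments[pid] == group1)
    c = sum(1 for pid in carriers if group_assignments[pid] == group2)
    return CarrierTable(a=a, b=n1 - a, c=c, d=n2 - c, group1=group1, group2=group2)


def carrier_association(t: CarrierTable) -> dict:
    """Fisher's exact test and odds ratio for a carrier table.

    Two-sided p sums all hypergeometric tables (fixed margins) at most as
    probable as the observed one; the one-sided p tests enrichment of
    carriers in group 1.  The odds ratio uses the Haldane-Anscombe 0.5
    correction when any cell is zero.
    """
    table = [[t.a, t.b], [t.c, t.d]]
    p_two = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    p_one = float(stats.fisher_exact(table, alternative="greater").pvalue)
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    return {
        "odds_ratio": odds_ratio,
        "fisher_p_two_sided": p_two,
        "fisher_p_one_sided": p_one,
    }


# ---------------------------------------------------------------------------
# table I/O

def _records_from_frame(df: pd.DataFrame) -> list[VariantRecord]:
    maf_cols = [c for c in df.columns if c.startswith("maf_")]
    pred_cols = {f"pred_{p}": p for p in PREDICTORS if f"pred_{p}" in df.columns}
    records = []
    for _, row in df.iterrows():
        maf = {
            c[len("maf_"):]: float(row[c])
            for c in maf_cols
            if pd.notna(row[c])
        }
        preds = {p: row[c] for c, p in pred_cols.items() if pd.notna(row[c])}
        raw_carriers = row.get("carrier_ids", "")
        carriers = tuple(
            x for x in str(raw_carriers).split(",") if x and x != "nan"
        ) if pd.notna(raw_carriers) else ()
        records.append(
            VariantRecord(
                variant_id=str(row["variant_id"]),
                protein_change=str(row.get("protein_change", "")),
                maf=maf,
                literature_pain_flag=bool(row.get("literature_pain_flag", False)),
                predictions=preds,
                carrier_ids=carriers,
            )
        )
    return records


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """Read a variant table (TSV, documented header) into records.

    Expected columns: ``variant_id``, optional ``protein_change``, any
    number of ``maf_<database>`` columns (empty = not observed),
    ``literature_pain_flag``, ``pred_<Predictor>`` columns, and a
    comma-separated ``carrier_ids`` column.
    """
    return _records_from_frame(pd.read_csv(path, sep="\t"))


def variants_frame(records) -> pd.DataFrame:
    dbs = sorted({db for v in records for db in v.maf})
    rows = []
    for v in records:
        rows.append(
            {
                "variant_id": v.variant_id,
                "protein_change": v.protein_change,
                **{f"maf_{db}": v.maf.get(db, np.nan) for db in dbs},
                "literature_pain_flag": v.literature_pain_flag,
                **{f"pred_{p}": v.predictions.get(p, "unknown") for p in PREDICTORS},
                "carrier_ids": ",".join(v.carrier_ids),
            }
        )
    return pd.DataFrame(rows)


def write_variants_tsv(records, path: str | Path) -> None:
    variants_frame(records).to_csv(path, sep="\t", index=False)


def read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    """Minimal VCF reader for interoperability.

    Uses CHROM/POS/REF/ALT plus INFO keys ``MAF_<DB>`` (floats),
    ``LITPAIN`` (flag), ``PRED_<Predictor>`` (strings) and ``CARRIERS``
    (comma-separated ids).
    """
    from cyvcf2 import VCF

    records = []
    pred_keys = {f"PRED_{p.upper()}": p for p in PREDICTORS}
    for var in VCF(str(path)):
        info = dict(var.INFO)
        maf = {
            key[len("MAF_"):].lower(): float(val)
            for key, val in info.items()
            if key.startswith("MAF_")
        }
        preds = {p: info[key] for key, p in pred_keys.items() if key in info}
        carriers = tuple(str(info.get("CARRIERS", "")).split(",")) if info.get("CARRIERS") else ()
        vid = var.ID or f"{var.CHROM}:{var.POS}:{var.REF}>{var.ALT[0]}"
        records.append(
            VariantRecord(
                variant_id=vid,
                protein_change=str(info.get("PCHANGE", "")),
                maf=maf,
                literature_pain_flag="LITPAIN" in info and bool(info["LITPAIN"]),
                predictions=preds,
                carrier_ids=carriers,
            )
        )
    return records
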