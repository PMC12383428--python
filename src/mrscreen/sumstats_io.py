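"""Reading, validation and harmonization of GWAS summary-statistic tables.

Summary statistics are exchanged as tab-separated text with one row per
variant and the canonical header::

    variant_id  effect_allele  other_allele  eaf  beta  se  pval  n

``beta`` is the additive effect per copy of the effect allele (log-odds for
binary traits), ``eaf`` the effect-allele frequency, ``n`` the sample size.
Alternative column dialects are supported through a column map.

Harmonization aligns an outcome (or mediator) table onto the exposure's
effect-allele orientation, the prerequisite of two-sample Mendelian
randomization: when the outcome row reports the opposite allele as the
effect allele its beta is negated and its frequency complemented.
Palindromic variants (A/T or C/G) whose strand cannot be resolved from the
alleles are kept only when the exposure frequency is far enough from 0.5
for frequency concordance to identify the strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

_VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

TRAIT_TYPES = ("exposure", "mediator", "outcome")

#: Default half-width of the exposure-frequency band around 0.5 inside which
#: palindromic variants are considered strand-ambiguous and dropped.
DEFAULT_PALINDROME_EAF_BAND = 0.08


class SumStatsError(ValueError):
    """Hard error in summary-statistic input (missing columns, duplicates...)."""


@dataclass(frozen=True)
class VariantAssoc:
    """One variant's association record for one trait."""

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def validation_error(self) -> str | None:
        """Reason this record violates the record invariants, or None."""
        if self.effect_allele not in _VALID_ALLELES:
            return f"invalid effect_allele {self.effect_allele!r}"
        if self.other_allele not in _VALID_ALLELES:
            return f"invalid other_allele {self.other_allele!r}"
        if self.effect_allele == self.other_allele:
            return "effect_allele equals other_allele"
        if not (0.0 < self.eaf < 1.0):
            return f"eaf {self.eaf} outside (0,1)"
        if not (self.se > 0.0):
            return f"se {self.se} not > 0"
        if not (0.0 < self.pval <= 1.0):
            return f"pval {self.pval} outside (0,1]"
        if not (self.n > 0):
            return f"n {self.n} not positive"
        if not np.isfinite(self.beta):
            return f"beta {self.beta} not finite"
        return None

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in _PALINDROMIC_PAIRS


@dataclass
class SumStatsTable:
    """Validated per-trait summary-statistic table.

    ``df`` holds the canonical columns; variant_id is unique. ``drop_log``
    records rows removed during validation as (variant_id, reason) pairs.
    """

    trait_id: str
    trait_type: str
    df: pd.DataFrame
    drop_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise SumStatsError(
                f"trait_type must be one of {TRAIT_TYPES}, got {self.trait_type!r}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.df["variant_id"])

    def records(self) -> Iterator[VariantAssoc]:
        for row in self.df.itertuples(index=False):
            yield VariantAssoc(
                variant_id=row.variant_id,
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                eaf=float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=int(row.n),
            )

    def record(self, variant_id: str) -> VariantAssoc:
        sub = self.df[self.df["variant_id"] == variant_id]
        if sub.empty:
            raise KeyError(variant_id)
        row = sub.iloc[0]
        return VariantAssoc(
            variant_id=row["variant_id"],
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
            eaf=float(row["eaf"]),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pval=float(row["pval"]),
            n=int(row["n"]),
        )


@dataclass
class LDMatrix:
    """Squared-correlation (r²) matrix over an ordered set of variants."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise SumStatsError(
                f"LD matrix shape {self.r2.shape} does not match {k} variant ids"
            )
        if len(set(self.variant_ids)) != k:
            raise SumStatsError("duplicate variant ids in LD matrix")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise SumStatsError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise SumStatsError("LD matrix diagonal is not 1")
        if (self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-12).any():
            raise SumStatsError("LD matrix entries outside [0,1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def submatrix(self, ids: Sequence[str]) -> "LDMatrix":
        missing = [v for v in ids if v not in self._index]
        if missing:
            raise SumStatsError(f"variants missing from LD matrix: {missing}")
        idx = [self._index[v] for v in ids]
        return LDMatrix(list(ids), self.r2[np.ix_(idx, idx)])


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs on a common effect-allele orientation.

    ``df`` columns: variant_id, beta_exp, se_exp, beta_out, se_out, eaf_exp.
    ``exclusions``: (variant_id, reason) for shared variants not retained.
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)


def _canonicalize(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SumStatsError(f"missing required column(s): {', '.join(missing)}")
    return df.loc[:, list(CANONICAL_COLUMNS)]


def read_sumstats(
    path,
    trait_id: str,
    trait_type: str,
    column_map: Mapping[str, str] | None = None,
) -> SumStatsTable:
    """Read and validate a summary-statistic TSV.

    Rows violating the per-record invariants are dropped and logged on the
    returned table's ``drop_log``. Duplicated variant ids and missing
    columns are hard errors; so is a table left empty by validation.

    Parameters
    ----------
    column_map
        Optional mapping ``canonical_name -> file_column_name`` for files in
        a non-canonical dialect.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    df = _canonicalize(raw, column_map)
    df = df.astype(
        {
            "variant_id": str,
            "effect_allele": str,
            "other_allele": str,
            "eaf": float,
            "beta": float,
            "se": float,
            "pval": float,
        }
    )
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()

    dup = df["variant_id"][df["variant_id"].duplicated()]
    if not dup.empty:
        raise SumStatsError(f"duplicated variant_id: {sorted(set(dup))}")

    drop_log: list[tuple[str, str]] = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            n_int = int(row.n)
            n_ok = float(row.n) == n_int
        except (TypeError, ValueError):
            n_int, n_ok = 0, False
        if not n_ok:
            drop_log.append((row.variant_id, f"n {row.n} not an integer"))
            keep[i] = False
            continue
        rec = VariantAssoc(
            row.variant_id, row.effect_allele, row.other_allele,
            float(row.eaf), float(row.beta), float(row.se), float(row.pval),
            n_int,
        )
        reason = rec.validation_error()
        if reason is not None:
            drop_log.append((row.variant_id, reason))
            keep[i] = False
    out = df.loc[keep].reset_index(drop=True)
    out["n"] = out["n"].astype(int)
    if out.empty:
        raise SumStatsError(f"no valid records remain in {path}")
    return SumStatsTable(trait_id, trait_type, out, drop_log)


def write_sumstats(table: SumStatsTable, path) -> None:
    """Write a table in the canonical TSV dialect.

    Floats are rendered with :func:`repr` so ``read_sumstats`` recovers them
    bit-equal (round-trip contract). Writing an empty table is a hard error.
    """
    if len(table.df) == 0:
        raise SumStatsError("refusing to write an empty summary-statistic table")
    df = table.df.copy()
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = df[col].map(lambda x: repr(float(x)))
    df.to_csv(path, sep="\t", index=False)


def read_ld_matrix(path) -> LDMatrix:
    """Read an LD matrix TSV: first row and column carry variant ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(v) for v in df.index]
    if list(df.columns) != ids:
        raise SumStatsError("LD matrix row and column ids disagree")
    return LDMatrix(ids, df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t"
    )


def _same_pair(a: VariantAssoc, ea: str, oa: str) -> bool:
    return a.effect_allele == ea and a.other_allele == oa


def harmonize(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    palindrome_eaf_band: float = DEFAULT_PALINDROME_EAF_BAND,
) -> HarmonizedSet:
    """Align outcome records onto the exposure effect-allele orientation.

    For each variant shared by both tables:

    * same allele pair, same orientation -> kept unchanged;
    * same pair, swapped orientation -> outcome beta negated, eaf complemented;
    * non-palindromic pair matching only through strand complement ->
      complemented and handled as above;
    * palindromic (A/T, C/G) with exposure EAF within
      ``0.5 ± palindrome_eaf_band`` -> excluded, reason "palindromic-ambiguous";
      outside the band, strand/orientation inferred by frequency concordance;
    * irreconcilable allele pairs -> excluded, reason "allele-mismatch".

    An empty variant-id intersection is a hard error.
    """
    out_by_id = {r.variant_id: r for r in outcome.records()}
    rows = []
    exclusions: list[tuple[str, str]] = []
    n_shared = 0
    for e in exposure.records():
        o = out_by_id.get(e.variant_id)
        if o is None:
            continue
        n_shared += 1
        if e.is_palindromic:
            pair_ok = {o.effect_allele, o.other_allele} == {
                e.effect_allele,
                e.other_allele,
            }
            if not pair_ok:
                exclusions.append((e.variant_id, "allele-mismatch"))
                continue
            if abs(e.eaf - 0.5) <= palindrome_eaf_band:
                exclusions.append((e.variant_id, "palindromic-ambiguous"))
                continue
            # Strand unresolvable from alleles: infer orientation from
            # frequency concordance with the exposure.
            flip = abs(o.eaf - e.eaf) > abs(o.eaf - (1.0 - e.eaf))
        elif _same_pair(o, e.effect_allele, e.other_allele):
            flip = False
        elif _same_pair(o, e.other_allele, e.effect_allele):
            flip = True
        elif _same_pair(
            o, _COMPLEMENT[e.effect_allele], _COMPLEMENT[e.other_allele]
        ):
            flip = False
        elif _same_pair(
            o, _COMPLEMENT[e.other_allele], _COMPLEMENT[e.effect_allele]
        ):
            flip = True
        else:
            exclusions.append((e.variant_id, "allele-mismatch"))
            continue
        beta_out = -o.beta if flip else o.beta
        rows.append(
            (e.variant_id, e.beta, e.se, beta_out, o.se, e.eaf)
        )
    if n_shared == 0:
        raise SumStatsError(
            f"no shared variants between {exposure.trait_id} and {outcome.trait_id}"
        )
    df = pd.DataFrame(
        rows,
        columns=["variant_id", "beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp"],
    )
    return HarmonizedSet(exposure.trait_id, outcome.trait_id, df, exclusions)
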