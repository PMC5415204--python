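"""Variant-keyed stability and phenotype tables.

Parsing, validation, aggregation and summaries for saturation-mutagenesis
free-energy predictions (ΔΔG, kcal/mol, positive = destabilizing) and the
per-variant cellular measurements they are compared against (steady-state
level, half-life, complex formation, survival, pathogenicity labels,
allele frequencies).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VARIANT_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")

__all__ = [
    "AMINO_ACIDS",
    "VariantKey",
    "DdgRecord",
    "DdgMatrix",
    "VariantParseError",
    "AggregationError",
    "parse_variant",
    "saturation_keys",
    "aggregate_ddg",
    "summarize_ddg",
    "subset_mean_ddg",
    "export_heatmap",
    "read_ddg_long_csv",
    "read_ddg_long_xlsx",
    "read_aggregated_ddg_csv",
    "read_phenotype_csv",
    "read_scores_csv",
    "read_labels_csv",
    "read_frequencies_csv",
    "load_msh2_table1",
]


class VariantParseError(ValueError):
    """A variant string does not describe a valid missense substitution."""


class AggregationError(ValueError):
    """Raw ΔΔG records cannot be reduced to one value per variant."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """A single missense substitution, e.g. ``L187P``.

    Positions are 1-based and follow the numbering of the input table
    (for the MSH2 dataset, the author numbering of the crystal structure);
    no renumbering is attempted.
    """

    wt_aa: str
    position: int
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in AMINO_ACIDS:
            raise VariantParseError(f"non-canonical wild-type residue {self.wt_aa!r}")
        if self.mut_aa not in AMINO_ACIDS:
            raise VariantParseError(f"non-canonical mutant residue {self.mut_aa!r}")
        if self.wt_aa == self.mut_aa:
            raise VariantParseError(
                f"wild-type and mutant residue are identical ({self.wt_aa}{self.position}{self.mut_aa})"
            )
        if self.position < 1:
            raise VariantParseError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


def parse_variant(text: str) -> VariantKey:
    """Parse a ``<wt><position><mut>`` variant string such as ``"L187P"``."""
    m = _VARIANT_RE.match(text.strip())
    if m is None:
        raise VariantParseError(f"malformed variant string {text!r}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return VariantKey(wt, pos, mut)


def saturation_keys(wt_sequence: str, start_position: int = 1) -> list[VariantKey]:
    """All 19 substitutions at every position of ``wt_sequence`` (19·P keys)."""
    keys: list[VariantKey] = []
    for offset, wt in enumerate(wt_sequence):
        if wt not in AMINO_ACIDS:
            raise VariantParseError(f"non-canonical residue {wt!r} at position {start_position + offset}")
        pos = start_position + offset
        keys.extend(VariantKey(wt, pos, mut) for mut in AMINO_ACIDS if mut != wt)
    return keys


@dataclass(frozen=True)
class DdgRecord:
    """One raw ΔΔG observation for a variant (optionally per replicate/chain)."""

    key: VariantKey
    ddg: float
    replicate_id: int | None = None
    chain_id: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.ddg):
            raise ValueError(f"non-finite ΔΔG for {self.key}")


class DdgMatrix:
    """Aggregated per-variant ΔΔG values over the resolved positions.

    Holds at most 19 entries per position; the wild-type identity at each
    position is inferred from the keys and must be consistent. Positions
    absent from the input are simply absent: querying them returns ``None``
    ("no prediction"), never 0.
    """

    def __init__(self, values: Mapping[VariantKey, float], provenance: str = "unspecified"):
        if not values:
            raise ValueError("empty ΔΔG matrix")
        wt_by_pos: dict[int, str] = {}
        per_pos_count: dict[int, int] = {}
        for key in values:
            seen = wt_by_pos.setdefault(key.position, key.wt_aa)
            if seen != key.wt_aa:
                raise AggregationError(
                    f"conflicting wild-type residues at position {key.position}: {seen} vs {key.wt_aa}"
                )
            per_pos_count[key.position] = per_pos_count.get(key.position, 0) + 1
        bad = [p for p, c in per_pos_count.items() if c > 19]
        if bad:
            raise AggregationError(f"more than 19 variants at position(s) {sorted(bad)}")
        self._values = dict(values)
        self._wt_by_pos = wt_by_pos
        self.provenance = provenance

    @property
    def positions(self) -> list[int]:
        return sorted(self._wt_by_pos)

    @property
    def wt_sequence(self) -> str:
        return "".join(self._wt_by_pos[p] for p in self.positions)

    def __len__(self) -> int:
        return len(self._values)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._values

    def ddg(self, key: VariantKey) -> float | None:
        """ΔΔG for ``key``, or ``None`` when the position carries no prediction."""
        return self._values.get(key)

    def items(self):
        return self._values.items()

    def wt_at(self, position: int) -> str | None:
        return self._wt_by_pos.get(position)

    def to_series(self) -> pd.Series:
        keys = sorted(self._values)
        return pd.Series(
            [self._values[k] for k in keys], index=[str(k) for k in keys], name="ddg", dtype=float
        )

    def to_frame(self) -> pd.DataFrame:
        s = self.to_series()
        return s.rename_axis("variant").reset_index()

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_series(cls, s: pd.Series, provenance: str = "unspecified") -> "DdgMatrix":
        return cls({parse_variant(v): float(x) for v, x in s.items()}, provenance=provenance)


def read_aggregated_ddg_csv(path) -> DdgMatrix:
    """Read an aggregated ΔΔG table (columns ``variant, ddg``)."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["variant", "ddg"], path)
    return DdgMatrix.from_series(df.set_index("variant")["ddg"], provenance=f"csv:{path}")


def read_ddg_long_csv(path) -> list[DdgRecord]:
    """Read a long-form raw ΔΔG table (variant, ddg[, replicate][, chain])."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["variant", "ddg"], path)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            DdgRecord(
                key=parse_variant(row.variant),
                ddg=float(row.ddg),
                replicate_id=int(row.replicate) if "replicate" in df.columns and pd.notna(row.replicate) else None,
                chain_id=str(row.chain) if "chain" in df.columns and pd.notna(row.chain) else None,
            )
        )
    return records


def read_ddg_long_xlsx(path, sheet_name=0, **kwargs) -> list[DdgRecord]:
    """Thin XLSX reader mapped onto the same long-form contract as the CSV."""
    import tempfile

    df = pd.read_excel(path, sheet_name=sheet_name, **kwargs)
    with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
        df.to_csv(fh.name, index=False)
        return read_ddg_long_csv(fh.name)


def aggregate_ddg(
    raw: Iterable[DdgRecord],
    scheme: str = "mean_over_replicates_then_chains",
    k: int | None = None,
    n: int | None = None,
    provenance: str | None = None,
) -> DdgMatrix:
    """Reduce raw per-replicate/per-chain ΔΔG records to one value per variant.

    Two schemes are supported, mirroring the two calculators' conventions:

    ``mean_over_replicates_then_chains``
        arithmetic mean over replicates within each chain, then the
        arithmetic mean over chains (with balanced data this equals the
        grand mean; the order matters for unbalanced input).
    ``lowest_k_of_n``
        the mean of the ``k`` smallest of exactly ``n`` values per variant.
    """
    df = pd.DataFrame(
        {
            "variant": [str(r.key) for r in raw],
            "ddg": [r.ddg for r in raw],
            "replicate": [r.replicate_id for r in raw],
            "chain": [r.chain_id if r.chain_id is not None else "" for r in raw],
        }
    )
    if df.empty:
        raise AggregationError("no records to aggregate")

    dup = df.duplicated(subset=["variant", "replicate", "chain"], keep=False)
    if dup.any():
        offenders = sorted(df.loc[dup, "variant"].unique())
        raise AggregationError(f"duplicate (variant, replicate, chain) cells for: {offenders}")

    if scheme == "mean_over_replicates_then_chains":
        per_chain = df.groupby(["variant", "chain"], sort=False)["ddg"].mean()
        agg = per_chain.groupby("variant", sort=False).mean()
        label = "mean_over_replicates_then_chains"
    elif scheme == "lowest_k_of_n":
        if k is None or n is None:
            raise AggregationError("lowest_k_of_n requires k and n")
        counts = df.groupby("variant")["ddg"].count()
        wrong = counts[counts != n]
        if not wrong.empty:
            raise AggregationError(
                f"lowest_{k}_of_{n} requires exactly {n} values per variant; offending: {sorted(wrong.index)}"
            )
        agg = df.groupby("variant")["ddg"].apply(lambda v: float(np.sort(v.to_numpy())[:k].mean()))
        label = f"lowest_{k}_of_{n}"
    else:
        raise AggregationError(f"unknown aggregation scheme {scheme!r}")

    prov = provenance or f"aggregated[{label}]"
    return DdgMatrix.from_series(agg, provenance=prov)


_COMPARATORS: dict[str, Callable[[np.ndarray, float], np.ndarray]] = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}


def summarize_ddg(
    matrix: DdgMatrix, thresholds: Sequence[tuple[str, float]] = ()
) -> dict:
    """Count, mean, and percentage of variants satisfying each threshold.

    Thresholds are (comparator, cutoff) pairs, e.g. ``("<", -1.0)``;
    percentages are over all stored variants.
    """
    values = np.array([v for _, v in matrix.items()], dtype=float)
    out = {"count": int(values.size), "mean": float(values.mean())}
    pct = {}
    for op, cutoff in thresholds:
        if op not in _COMPARATORS:
            raise ValueError(f"unknown comparator {op!r}")
        pct[f"{op}{cutoff:g}"] = float(100.0 * _COMPARATORS[op](values, cutoff).mean())
    out["percent"] = pct
    return out


def subset_mean_ddg(
    table: pd.DataFrame, predicate: Callable[[pd.DataFrame], pd.Series] | pd.Series
) -> tuple[float, float, int]:
    """Mean ± SEM of the ``ddg`` column over a phenotype-selected subset.

    ``predicate`` is either a boolean mask aligned with ``table`` or a
    callable producing one. SEM uses the n−1 sample standard deviation.
    Returns ``(mean, sem, n)``; raises if fewer than 2 variants match.
    """
    mask = predicate(table) if callable(predicate) else predicate
    sub = table.loc[np.asarray(mask, dtype=bool), "ddg"].astype(float)
    if len(sub) < 2:
        raise ValueError(f"predicate selects {len(sub)} variants; need at least 2")
    mean = float(sub.mean())
    sem = float(sub.std(ddof=1) / np.sqrt(len(sub)))
    return mean, sem, int(len(sub))


def export_heatmap(matrix: DdgMatrix, cap: float = 7.0) -> pd.DataFrame:
    """Position × residue grid for display, destabilization clipped at ``+cap``.

    Rows are the 20 residues, columns the resolved positions. Wild-type
    cells are marked NaN (no substitution); clipping is one-sided and
    applies to the rendered grid only — the matrix itself is untouched.
    """
    positions = matrix.positions
    grid = pd.DataFrame(np.nan, index=list(AMINO_ACIDS), columns=positions)
    for key, value in matrix.items():
        grid.at[key.mut_aa, key.position] = min(value, cap)
    return grid


def render_heatmap(grid: pd.DataFrame, path, cmap: str = "coolwarm") -> None:
    """Optional image rendering of an exported heat-map grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.12 * grid.shape[1]), 5))
    im = ax.imshow(grid.to_numpy(dtype=float), aspect="auto", cmap=cmap)
    ax.set_yticks(range(len(grid.index)), grid.index)
    ax.set_xlabel("position")
    fig.colorbar(im, ax=ax, label="ΔΔG (kcal/mol, capped)")
    fig.savefig(path, dpi=150)
    plt.close(fig)


# --- phenotype / score / label / frequency tables -------------------------

_MSH6_CATEGORIES = {"yes", "weak", "no"}
_NUCLEAR_CATEGORIES = {"yes", "partial"}


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-variant phenotype table (wild type row excluded)."""
    df = df.copy()
    for v in df["variant"]:
        parse_variant(v)
    if (df["level"].dropna() < 0).any():
        raise ValueError("steady-state levels must be >= 0")
    if "half_life_h" in df.columns and (df["half_life_h"].dropna() <= 0).any():
        raise ValueError("half-lives must be > 0")
    if "msh6_interaction" in df.columns:
        bad = set(df["msh6_interaction"].dropna().str.lower()) - _MSH6_CATEGORIES
        if bad:
            raise ValueError(f"unknown MSH6 interaction categories: {sorted(bad)}")
    if "nuclear" in df.columns:
        bad = set(df["nuclear"].dropna().str.lower()) - _NUCLEAR_CATEGORIES
        if bad:
            raise ValueError(f"unknown nuclear-localization categories: {sorted(bad)}")
    if "survival_pct" in df.columns:
        s = df["survival_pct"].dropna()
        if ((s < 0) | (s > 100)).any():
            raise ValueError("survival_pct must lie in [0, 100]")
    return df


def read_phenotype_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["variant", "level"], path)
    return validate_phenotypes(df)


def read_scores_csv(path) -> pd.DataFrame:
    """Long-form predictor score table: variant, predictor, score, higher_is_damaging."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["variant", "predictor", "score"], path)
    if "higher_is_damaging" not in df.columns:
        df["higher_is_damaging"] = True
    for v in df["variant"]:
        parse_variant(v)
    return df


def read_labels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["variant", "label"], path)
    bad = set(df["label"]) - {"pathogenic", "non_pathogenic"}
    if bad:
        raise ValueError(f"{path}: labels must be pathogenic/non_pathogenic, got {sorted(bad)}")
    conflicted = df.groupby("variant")["label"].nunique()
    if (conflicted > 1).any():
        raise ValueError(f"conflicting labels for {sorted(conflicted[conflicted > 1].index)}")
    return df.drop_duplicates(subset=["variant"])


def read_frequencies_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["variant", "allele_frequency"], path)
    f = df["allele_frequency"]
    if ((f < 0) | (f > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    return df


def load_msh2_table1(include_wt: bool = False) -> pd.DataFrame:
    """The bundled per-variant MSH2 characterization table (24 mutants).

    Columns: variant, ddg (FoldX, kcal/mol), solvent accessibility (%),
    half-life (h) ± sd, nuclear localization, MSH6 interaction category,
    patient-found flag, temperature-sensitivity annotation. The wild-type
    reference row (ΔΔG = 0, half-life 19 h) is returned only when
    ``include_wt=True``.
    """
    with resources.files("mutstab.data").joinpath("msh2_table1.csv").open() as fh:
        df = pd.read_csv(fh)
    df["patient_found"] = df["patient_found"].astype(bool)
    if not include_wt:
        df = df[df["variant"] != "WT"].reset_index(drop=True)
    return df
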