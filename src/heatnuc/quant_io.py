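"""Tabular I/O and basic transforms for abundance matrices.

All tables are UTF-8 TSV with a header row.  Missing intensities are
encoded as empty fields, never as 0: a zero intensity is informative
censoring and is treated separately (``log2_transform`` maps it to
missing).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "CONDITION_ORDER",
    "SampleDesign",
    "AbundanceMatrix",
    "TranscriptCounts",
    "read_design",
    "read_abundance",
    "write_abundance",
    "read_peptides",
    "read_transcript_counts",
    "aggregate_peptides",
    "rpm_normalize",
    "log2_transform",
    "presence_filter",
    "impute_left_censored",
    "median_center",
]


class Condition(str, enum.Enum):
    """The four experimental conditions, in time order."""

    T22 = "T22"   # control, 22 degC
    H4 = "H4"     # 37 degC, 4 h
    H24 = "H24"   # 37 degC, 24 h
    R22 = "R22"   # recovery at 22 degC

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CONDITION_ORDER: tuple[Condition, ...] = (
    Condition.T22,
    Condition.H4,
    Condition.H24,
    Condition.R22,
)

#: Built-in aliases accepted by :func:`read_design` (matched case-insensitively,
#: after stripping spaces and degree signs).
_DEFAULT_ALIASES: dict[str, Condition] = {
    "t22": Condition.T22,
    "22": Condition.T22,
    "22c": Condition.T22,
    "ctrl": Condition.T22,
    "control": Condition.T22,
    "mock": Condition.T22,
    "h4": Condition.H4,
    "37c_4h": Condition.H4,
    "37_4h": Condition.H4,
    "4h": Condition.H4,
    "h24": Condition.H24,
    "37c_24h": Condition.H24,
    "37_24h": Condition.H24,
    "24h": Condition.H24,
    "r22": Condition.R22,
    "r22c": Condition.R22,
    "recovery": Condition.R22,
}


@dataclass(frozen=True)
class SampleDesign:
    """Maps sample ids to conditions and replicate numbers."""

    samples: tuple[str, ...]
    conditions: tuple[Condition, ...]
    replicates: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.samples) != len(set(self.samples)):
            dupes = sorted(
                {s for s in self.samples if list(self.samples).count(s) > 1}
            )
            raise ValueError(f"duplicate sample_id(s): {dupes}")
        if not (len(self.samples) == len(self.conditions) == len(self.replicates)):
            raise ValueError("samples, conditions and replicates must align")
        for r in self.replicates:
            if r < 1:
                raise ValueError(f"replicate index must be >= 1, got {r}")

    def __len__(self) -> int:
        return len(self.samples)

    def samples_for(self, condition: Condition) -> list[str]:
        return [
            s for s, c in zip(self.samples, self.conditions) if c == condition
        ]

    def present_conditions(self) -> list[Condition]:
        seen = dict.fromkeys(self.conditions)
        return list(seen)

    def require_conditions(self, needed: Iterable[Condition]) -> None:
        present = set(self.conditions)
        for c in needed:
            if c not in present:
                raise ValueError(f"condition {c.value} absent from design")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.samples,
                "condition": [c.value for c in self.conditions],
                "replicate": self.replicates,
            }
        )

    @classmethod
    def default(cls, n_replicates: int = 3) -> "SampleDesign":
        """The canonical 4-condition x n-replicate design."""
        samples, conds, reps = [], [], []
        for c in CONDITION_ORDER:
            for r in range(1, n_replicates + 1):
                samples.append(f"{c.value}_{r}")
                conds.append(c)
                reps.append(r)
        return cls(tuple(samples), tuple(conds), tuple(reps))


@dataclass
class AbundanceMatrix:
    """Features x samples matrix with NaN for missing values.

    ``data`` rows are keyed by accession (proteins) or gene id
    (transcripts); ``scale`` is one of ``raw``, ``log2`` or ``rpm`` and is
    propagated through transforms.
    """

    data: pd.DataFrame
    scale: str = "raw"
    meta: dict = field(default_factory=dict)

    _SCALES = ("raw", "log2", "rpm")

    def __post_init__(self) -> None:
        if self.scale not in self._SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate row keys: {list(dupes)[:5]}")
        vals = self.data.to_numpy(dtype=float)
        if self.scale in ("raw", "rpm") and np.nanmin(vals, initial=0.0) < 0:
            raise ValueError(f"negative values not allowed on {self.scale} scale")
        if self.scale == "log2" and np.isneginf(vals).any():
            raise ValueError("-inf not allowed on log2 scale; use missing")

    @property
    def accessions(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def check_design(self, design: SampleDesign) -> None:
        missing = [s for s in self.samples if s not in design.samples]
        if missing:
            raise ValueError(f"samples not in design: {missing}")


@dataclass
class TranscriptCounts:
    """Integer count matrix plus per-sample totals of mapped reads."""

    counts: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype("int64")
        self.totals = self.totals.astype("int64").reindex(self.counts.columns)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.totals.isna().any():
            missing = list(self.totals.index[self.totals.isna()])
            raise ValueError(f"totals missing for samples: {missing}")
        if (self.totals <= 0).any():
            bad = list(self.totals.index[self.totals <= 0])
            raise ValueError(f"total_mapped_reads must be > 0; offending: {bad}")
        over = self.counts.gt(self.totals, axis=1)
        if over.to_numpy().any():
            raise ValueError("count exceeds total_mapped_reads")


# ---------------------------------------------------------------------------
# readers / writers


def _normalise_condition_token(tok: str) -> str:
    return (
        tok.strip()
        .lower()
        .replace("°", "")
        .replace("degc", "c")
        .replace(" ", "_")
    )


def read_design(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> SampleDesign:
    """Read a ``sample, condition, replicate`` TSV into a SampleDesign.

    Condition labels are matched case-insensitively against the canonical
    names, a built-in alias table, and any user ``aliases`` mapping
    (label -> canonical condition name).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "condition", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"design file must have columns {sorted(required)}, got {list(df.columns)}"
        )
    alias_map = dict(_DEFAULT_ALIASES)
    if aliases:
        for k, v in aliases.items():
            alias_map[_normalise_condition_token(k)] = Condition(v.upper())
    conds = []
    for i, raw in enumerate(df["condition"]):
        tok = _normalise_condition_token(str(raw))
        candidates = (tok, tok.replace("_", ""))
        hit = next(
            (
                c
                for c in candidates
                if c.upper() in Condition.__members__ or c in alias_map
            ),
            None,
        )
        if hit is not None:
            conds.append(
                Condition[hit.upper()]
                if hit.upper() in Condition.__members__
                else alias_map[hit]
            )
        else:
            raise ValueError(
                f"unknown condition label {raw!r} in design row {i + 2} "
                f"(sample {df['sample'].iloc[i]!r})"
            )
    return SampleDesign(
        samples=tuple(df["sample"].astype(str)),
        conditions=tuple(conds),
        replicates=tuple(int(r) for r in df["replicate"]),
    )


def read_abundance(path: str | Path, scale: str = "raw") -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return AbundanceMatrix(df.astype(float), scale=scale)


def write_abundance(m: AbundanceMatrix, path: str | Path) -> None:
    out = m.data.copy()
    out.index.name = out.index.name or "accession"
    # repr-precision float formatting so read-back reproduces values
    out.to_csv(path, sep="\t", na_rep="", float_format="%.12g")


def read_peptides(path: str | Path) -> pd.DataFrame:
    """Read a peptide table keyed by (peptide_id, protein_accession)."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str, "protein_accession": str})
    for col in ("peptide_id", "protein_accession"):
        if col not in df.columns:
            raise ValueError(f"peptide table missing column {col!r}")
    return df.set_index(["peptide_id", "protein_accession"]).astype(float)


def read_transcript_counts(
    counts_path: str | Path, totals_path: str | Path
) -> TranscriptCounts:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    totals = pd.read_csv(totals_path, sep="\t")
    if not {"sample", "total_mapped_reads"}.issubset(totals.columns):
        raise ValueError("totals file must have columns sample, total_mapped_reads")
    totals = totals.set_index("sample")["total_mapped_reads"]
    return TranscriptCounts(counts, totals)


# ---------------------------------------------------------------------------
# transforms


def aggregate_peptides(peps: pd.DataFrame, design: SampleDesign) -> AbundanceMatrix:
    """Sum observed peptide abundances per protein and sample.

    A protein value is missing (NaN) only when *all* its peptides are
    missing in that sample; otherwise missing peptides are simply
    excluded from the sum.
    """
    accs = peps.index.get_level_values("protein_accession")
    if (accs.astype(str).str.strip() == "").any():
        raise ValueError("peptide mapped to empty protein_accession")
    vals = peps.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValueError("negative peptide abundance")
    grouped = peps.groupby(level="protein_accession", sort=True)
    summed = grouped.sum(min_count=1)  # min_count=1: all-NaN stays NaN
    m = AbundanceMatrix(summed, scale="raw")
    m.check_design(design)
    return m


def rpm_normalize(tc: TranscriptCounts) -> AbundanceMatrix:
    """Counts scaled to reads-per-million of each sample's mapped total."""
    rpm = tc.counts.div(tc.totals, axis=1) * 1e6
    return AbundanceMatrix(rpm, scale="rpm")


def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """log2 of positive values; zeros become missing (left censoring)."""
    if m.scale == "log2":
        raise ValueError("matrix already on log2 scale")
    vals = m.data.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValueError("negative input to log2_transform")
    with np.errstate(divide="ignore"):
        out = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    return AbundanceMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        scale="log2",
        meta=dict(m.meta, source_scale=m.scale),
    )


def presence_filter(
    m: AbundanceMatrix,
    design: SampleDesign,
    min_per_condition: int = 2,
    mode: str = "any_condition",
) -> AbundanceMatrix:
    """Drop rows with too few observed values.

    ``any_condition`` keeps a row if at least one condition has
    >= ``min_per_condition`` observed replicates.  ``all_conditions``
    requires it in every condition present in the design.  Per-contrast
    testability is evaluated downstream regardless.
    """
    if min_per_condition == 0:
        return m
    if mode not in ("any_condition", "all_conditions"):
        raise ValueError(f"unknown presence-filter mode {mode!r}")
    counts = {}
    for c in design.present_conditions():
        cols = [s for s in design.samples_for(c) if s in m.data.columns]
        if len(cols) < min_per_condition:
            raise ValueError(
                f"min_per_condition={min_per_condition} exceeds replicate "
                f"count for {c.value}"
            )
        counts[c] = m.data[cols].notna().sum(axis=1)
    tab = pd.DataFrame(counts)
    if mode == "any_condition":
        keep = (tab >= min_per_condition).any(axis=1)
    else:
        keep = (tab >= min_per_condition).all(axis=1)
    return AbundanceMatrix(
        m.data.loc[keep],
        scale=m.scale,
        meta=dict(m.meta, presence_filter=f"{mode}:{min_per_condition}"),
    )


def impute_left_censored(
    m: AbundanceMatrix,
    design: SampleDesign,
    quantile: float = 0.01,
    spread: float = 0.3,
    seed: int = 0,
) -> AbundanceMatrix:
    """Replace missing log2 values with draws near each sample's low quantile.

    Stands in for a deterministic-software imputation step whose exact
    settings are not public; OFF by default in the pipeline (statistics
    use available-case analysis per contrast).
    """
    if m.scale != "log2":
        raise ValueError("imputation requires log2 scale")
    rng = np.random.default_rng(seed)
    out = m.data.copy()
    for col in out.columns:
        obs = out[col].dropna()
        if len(obs) < 10:
            raise ValueError(
                f"sample {col!r} has only {len(obs)} observed values; "
                "quantile imputation unreliable"
            )
        n_missing = out[col].isna().sum()
        if n_missing == 0:
            continue
        centre = float(obs.quantile(quantile))
        fill = rng.normal(centre, spread, size=n_missing)
        out.loc[out[col].isna(), col] = fill
    return AbundanceMatrix(
        out, scale="log2", meta=dict(m.meta, imputed=f"q={quantile},sd={spread}")
    )


def median_center(m: AbundanceMatrix) -> AbundanceMatrix:
    """Optional per-sample median centering on log2 scale (config flag)."""
    if m.scale != "log2":
        raise ValueError("median centering requires log2 scale")
    med = m.data.median(axis=0, skipna=True)
    grand = float(med.mean())
    out = m.data.sub(med - grand, axis=1)
    return AbundanceMatrix(out, scale="log2", meta=dict(m.meta, median_centered=True))
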