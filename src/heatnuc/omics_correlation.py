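"""Protein vs transcript condition-profile correlation and categorization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant_io import CONDITION_ORDER, AbundanceMatrix, SampleDesign

__all__ = [
    "MatchedProfiles",
    "match_condition_profiles",
    "pearson_correlation",
    "categorize",
    "correlate",
    "category_proportions",
]

CATEGORIES = ("positive", "uncorrelated", "negative")


@dataclass
class MatchedProfiles:
    """Per-gene protein and transcript 4-condition profiles, same order."""

    protein: pd.DataFrame  # genes x 4 conditions, mean log2 abundance
    transcript: pd.DataFrame  # genes x 4 conditions, mean log2(rpm + 1)
    dropped_protein_only: list[str]
    dropped_rna_only: list[str]


def _per_condition_means(
    m: AbundanceMatrix, design: SampleDesign, log_pseudocount: float | None
) -> pd.DataFrame:
    data = m.data
    if log_pseudocount is not None:
        if m.scale == "log2":
            raise ValueError("pseudocount log transform expects a linear-scale matrix")
        data = np.log2(data + log_pseudocount)
    elif m.scale != "log2":
        raise ValueError("matrix must be log2 scale (or pass a pseudocount)")
    cols = {}
    for c in CONDITION_ORDER:
        ids = [s for s in design.samples_for(c) if s in data.columns]
        if not ids:
            raise ValueError(f"no samples for condition {c.value}")
        cols[c.value] = data[ids].mean(axis=1, skipna=True)
    return pd.DataFrame(cols)


def match_condition_profiles(
    prot: AbundanceMatrix,
    prot_design: SampleDesign,
    rna: AbundanceMatrix,
    rna_design: SampleDesign,
    id_map: pd.Series | None = None,
    rna_pseudocount: float = 1.0,
) -> MatchedProfiles:
    """Join per-condition protein and transcript profiles by gene id.

    ``id_map`` optionally translates protein accessions to transcript
    gene ids (index = accession, values = gene_id).  Transcript values
    enter as log2(rpm + pseudocount); set ``rna_pseudocount`` to None if
    the transcript matrix is already on log2 scale.
    """
    p = _per_condition_means(
        prot, prot_design, None if prot.scale == "log2" else 1.0
    )
    r = _per_condition_means(rna, rna_design, rna_pseudocount)
    if id_map is not None:
        p = p.rename(index=id_map.to_dict())
    shared = p.index.intersection(r.index)
    if len(shared) == 0:
        raise ValueError("no shared gene ids between protein and transcript tables")
    return MatchedProfiles(
        protein=p.loc[shared],
        transcript=r.loc[shared],
        dropped_protein_only=sorted(p.index.difference(r.index)),
        dropped_rna_only=sorted(r.index.difference(p.index)),
    )


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r of two equal-length profiles; NaN for a constant input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def categorize(r: float, positive_cut: float = 0.5, negative_cut: float = -0.5) -> str:
    """positive if r >= 0.5, negative if r <= -0.5 (both inclusive)."""
    if np.isnan(r):
        return "uncorrelated"  # constant profile convention
    if not (-1.0 <= r <= 1.0):
        raise ValueError(f"r must be in [-1, 1], got {r}")
    if r >= positive_cut:
        return "positive"
    if r <= negative_cut:
        return "negative"
    return "uncorrelated"


def correlate(pairs: MatchedProfiles) -> pd.DataFrame:
    """Per-gene Pearson r and category over the 4 matched conditions."""
    records = []
    pm = pairs.protein.to_numpy(dtype=float)
    tm = pairs.transcript.to_numpy(dtype=float)
    for i, gene in enumerate(pairs.protein.index):
        r = pearson_correlation(pm[i], tm[i])
        records.append(
            {
                "gene_id": str(gene),
                "r": r,
                "category": categorize(r),
                "constant_flag": bool(np.isnan(r)),
            }
        )
    return pd.DataFrame(records)


def category_proportions(
    records: pd.DataFrame, bins: int = 40
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Category fractions (exact, from counts) plus a binned density of r."""
    if len(records) == 0:
        raise ValueError("no correlation records")
    n = len(records)
    rows = [
        {
            "category": cat,
            "count": int((records["category"] == cat).sum()),
            "fraction": float((records["category"] == cat).sum()) / n,
        }
        for cat in CATEGORIES
    ]
    props = pd.DataFrame(rows)
    edges = np.linspace(-1.0, 1.0, bins + 1)
    counts, _ = np.histogram(records["r"].dropna(), bins=edges)
    density = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "density": counts / max(counts.sum(), 1) / (2.0 / bins),
        }
    )
    return props, density
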