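"""Seeded synthetic data with planted kinetic classes and ground truth.

Emulates the structure of the real experiment — 4 conditions x 3
replicates, a few thousand proteins, left-censored missing intensities —
and produces matched negative-binomial transcript counts with a tunable
protein-mRNA coupling, so every downstream module can be exercised as a
parameter-recovery problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant_io import (
    CONDITION_ORDER,
    AbundanceMatrix,
    SampleDesign,
    TranscriptCounts,
)

__all__ = [
    "SimulationConfig",
    "class_mean_profiles",
    "simulate_proteome",
    "split_into_peptides",
    "simulate_transcripts",
    "evaluate_recovery",
    "KINETIC_CLASSES",
]

#: Classes with a planted effect profile; NULL proteins are flat.
KINETIC_CLASSES = ("EG", "LG", "TG", "EPG", "LPG", "RG", "CG")


def class_mean_profiles(delta: float) -> dict[str, np.ndarray]:
    """Per-class offsets from baseline, order (T22, H4, H24, R22).

    The six major kinetic groups follow their defining on/off timing;
    CG ramps continuously; NULL is flat.  Direction -1 negates offsets.
    """
    if not delta > 0:
        raise ValueError("delta must be > 0")
    d = float(delta)
    return {
        "EG": np.array([0.0, d, d, 0.0]),
        "LG": np.array([0.0, 0.0, d, 0.0]),
        "TG": np.array([0.0, d, 0.0, 0.0]),
        "EPG": np.array([0.0, d, d, d]),
        "LPG": np.array([0.0, 0.0, d, d]),
        "RG": np.array([0.0, 0.0, 0.0, d]),
        "CG": np.array([0.0, d / 3.0, 2.0 * d / 3.0, d]),
        "NULL": np.zeros(4),
    }


@dataclass
class SimulationConfig:
    """Everything the generator needs; all randomness flows from ``seed``."""

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {c: 30 for c in KINETIC_CLASSES} | {"NULL": 2000}
    )
    frac_up: float = 0.8  # direction mix for planted classes
    delta: float = 2.0  # effect size, log2 units
    sigma: float = 0.3  # replicate noise sd, log2 units
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    n_replicates: int = 3
    lod_quantile: float = 0.0  # left-censoring threshold (0 disables)
    mcar_rate: float = 0.0
    # transcript model
    nb_dispersion: float = 0.05
    library_size: int = 5_000_000
    rna_amplitude: float = 1.5  # log2 swing of transcript profiles
    rho_per_class: dict[str, float] = field(default_factory=dict)
    rho_default: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (("frac_up", self.frac_up), ("mcar_rate", self.mcar_rate),
                          ("lod_quantile", self.lod_quantile)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        for cls in self.n_per_class:
            if cls != "NULL" and cls not in KINETIC_CLASSES:
                raise ValueError(f"unknown class {cls!r}")

    def design(self) -> SampleDesign:
        return SampleDesign.default(self.n_replicates)


def _truth_frame(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    profiles = class_mean_profiles(cfg.delta)
    rows = []
    i = 0
    for cls in (*KINETIC_CLASSES, "NULL"):
        n = cfg.n_per_class.get(cls, 0)
        for _ in range(n):
            acc = f"P{i:05d}"
            if cls == "NULL":
                direction = 0
            else:
                direction = 1 if rng.random() < cfg.frac_up else -1
            baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd)
            offsets = profiles[cls] * (direction if direction else 1)
            means = baseline + offsets
            rows.append(
                {
                    "accession": acc,
                    "class": cls,
                    "direction": direction,
                    **{
                        f"mu_{c.value}": means[j]
                        for j, c in enumerate(CONDITION_ORDER)
                    },
                }
            )
            i += 1
    return pd.DataFrame(rows).set_index("accession")


def simulate_proteome(
    cfg: SimulationConfig,
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Raw-scale intensity matrix plus the planted-truth table.

    log2 value = baseline + class offset + N(0, sigma^2) per replicate;
    a value goes missing when it falls below its sample's
    ``lod_quantile`` of log2 intensities (left censoring) or by an MCAR
    coin flip.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = _truth_frame(cfg, rng)
    design = cfg.design()
    mu_cols = [f"mu_{c.value}" for c in CONDITION_ORDER]
    mu = truth[mu_cols].to_numpy()  # n_prot x 4
    cond_index = {c: j for j, c in enumerate(CONDITION_ORDER)}
    col_mu = np.column_stack(
        [mu[:, cond_index[c]] for c in design.conditions]
    )  # n_prot x n_samples
    log2_vals = col_mu + rng.normal(0.0, cfg.sigma, size=col_mu.shape)
    missing = np.zeros(log2_vals.shape, dtype=bool)
    if cfg.lod_quantile > 0:
        lod = np.quantile(log2_vals, cfg.lod_quantile, axis=0)
        missing |= log2_vals < lod
    if cfg.mcar_rate > 0:
        missing |= rng.random(log2_vals.shape) < cfg.mcar_rate
    intensities = np.power(2.0, log2_vals)
    intensities[missing] = np.nan
    m = AbundanceMatrix(
        pd.DataFrame(intensities, index=truth.index, columns=design.samples),
        scale="raw",
        meta={"seed": cfg.seed, "generator": "simulate_proteome"},
    )
    return m, truth.reset_index()


def split_into_peptides(
    m: AbundanceMatrix, seed: int, max_peptides: int = 10
) -> pd.DataFrame:
    """Spawn 1..max_peptides peptides per protein summing to its intensity.

    Peptide proportions are Dirichlet-distributed, shared across
    samples; a protein's missing sample yields missing peptides.
    """
    if m.scale != "raw":
        raise ValueError("peptide split requires raw scale")
    rng = np.random.default_rng(seed)
    rows = []
    index = []
    for acc in m.data.index:
        k = int(rng.integers(1, max_peptides + 1))
        props = rng.dirichlet(np.ones(k))
        vals = m.data.loc[acc].to_numpy(dtype=float)
        for j in range(k):
            rows.append(vals * props[j])
            index.append((f"{acc}_pep{j + 1}", acc))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(
            index, names=["peptide_id", "protein_accession"]
        ),
        columns=m.data.columns,
    )


def simulate_transcripts(
    truth: pd.DataFrame, cfg: SimulationConfig
) -> tuple[TranscriptCounts, SampleDesign, pd.DataFrame]:
    """Matched NB counts whose log profiles couple to the protein truth.

    Per gene, the latent log2 profile is rho * (standardized true
    protein profile) + sqrt(1 - rho^2) * independent standard noise,
    scaled by ``rna_amplitude``; counts are negative binomial around
    library_size-scaled means.  Returns counts, the RNA sample design
    and a per-gene table of the coupling targets actually used.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    design = SampleDesign(
        samples=tuple(
            f"RNA_{c.value}_{r}"
            for c in CONDITION_ORDER
            for r in range(1, cfg.n_replicates + 1)
        ),
        conditions=tuple(
            c for c in CONDITION_ORDER for _ in range(cfg.n_replicates)
        ),
        replicates=tuple(
            r for _ in CONDITION_ORDER for r in range(1, cfg.n_replicates + 1)
        ),
    )
    mu_cols = [f"mu_{c.value}" for c in CONDITION_ORDER]
    prot = truth.set_index("accession")[mu_cols].to_numpy()
    classes = truth["class"].to_numpy()
    rho = np.array(
        [cfg.rho_per_class.get(c, cfg.rho_default) for c in classes]
    )
    sd = prot.std(axis=1, keepdims=True)
    z = np.where(
        sd > 0, (prot - prot.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0), 0.0
    )
    noise = rng.normal(size=z.shape)
    nsd = noise.std(axis=1, keepdims=True)
    noise = (noise - noise.mean(axis=1, keepdims=True)) / np.where(nsd > 0, nsd, 1.0)
    latent = rho[:, None] * z + np.sqrt(1.0 - rho[:, None] ** 2) * noise
    log2_rpm = 6.0 + cfg.rna_amplitude * latent  # ~64 rpm baseline
    mean_rpm = np.power(2.0, log2_rpm)

    n_samples = len(design)
    counts = np.empty((len(truth), n_samples), dtype=np.int64)
    cond_index = {c: j for j, c in enumerate(CONDITION_ORDER)}
    for s, cond in enumerate(design.conditions):
        mean_counts = mean_rpm[:, cond_index[cond]] * cfg.library_size / 1e6
        if cfg.nb_dispersion > 0:
            size = 1.0 / cfg.nb_dispersion
            p = size / (size + mean_counts)
            counts[:, s] = rng.negative_binomial(size, p)
        else:
            counts[:, s] = np.rint(mean_counts).astype(np.int64)
    genes = truth["accession"].tolist()
    tc = TranscriptCounts(
        pd.DataFrame(counts, index=genes, columns=design.samples),
        pd.Series(cfg.library_size, index=design.samples, name="total_mapped_reads"),
    )
    coupling = pd.DataFrame({"gene_id": genes, "rho_target": rho})
    return tc, design, coupling


def evaluate_recovery(
    assignments: pd.DataFrame, truth: pd.DataFrame
) -> dict:
    """Precision/recall per class, overall accuracy, confusion matrix.

    ``assignments`` has columns accession, group (UNASSIGNED allowed);
    proteins absent from assignments count as UNASSIGNED.  Truth classes
    CG and NULL map to expected labels UNASSIGNED (CG is recovered by
    clustering, not the decision table).  Also reports the realized
    false-discovery proportion of the differential stage: the fraction
    of the assignment universe (the DAP set) that is truly NULL.
    """
    t = truth.set_index("accession")
    pred = dict(zip(assignments["accession"], assignments["group"]))
    labels = {}
    for acc, cls in t["class"].items():
        expected = cls if cls in ("EG", "LG", "TG", "EPG", "LPG", "RG") else "UNASSIGNED"
        labels[acc] = (expected, pred.get(acc, "UNASSIGNED"))
    classes = ("EG", "LG", "TG", "EPG", "LPG", "RG", "UNASSIGNED")
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for expected, got in labels.values():
        confusion.loc[expected, got] += 1
    per_class = {}
    for c in classes:
        tp = int(confusion.loc[c, c])
        fn = int(confusion.loc[c].sum()) - tp
        fp = int(confusion[c].sum()) - tp
        per_class[c] = {
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
        }
    correct = sum(int(e == g) for e, g in labels.values())
    null_accs = set(t.index[t["class"] == "NULL"])
    dap_accs = set(assignments["accession"])
    fdp = len(dap_accs & null_accs) / len(dap_accs) if dap_accs else 0.0
    return {
        "accuracy": correct / len(labels),
        "per_class": per_class,
        "confusion": confusion,
        "differential_fdp": fdp,
    }
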