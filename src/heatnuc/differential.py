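"""Pairwise differential abundance with empirical-Bayes variance moderation.

Six canonical contrasts between the four conditions are tested with a
two-sample moderated t-statistic: per-protein pooled variances are shrunk
toward a prior variance ``s0_sq`` with prior degrees of freedom ``d0``,
both estimated across proteins by moment matching of log sample variances
to a scaled F distribution (digamma/trigamma inversion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .quant_io import AbundanceMatrix, Condition, SampleDesign

__all__ = [
    "Contrast",
    "CONTRASTS",
    "VariancePrior",
    "ContrastThresholds",
    "pooled_stats",
    "fit_variance_prior",
    "moderated_t",
    "storey_pi0",
    "adjust_pvalues",
    "call_significance",
    "run_contrasts",
    "contrast_summary",
    "dap_set",
]


@dataclass(frozen=True)
class Contrast:
    id: str
    numerator: Condition
    denominator: Condition

    @property
    def label(self) -> str:
        return f"{self.numerator.value}_vs_{self.denominator.value}"


#: The canonical six pairwise comparisons, in fixed order C1..C6.
CONTRASTS: tuple[Contrast, ...] = (
    Contrast("C1", Condition.H4, Condition.T22),
    Contrast("C2", Condition.H24, Condition.T22),
    Contrast("C3", Condition.R22, Condition.T22),
    Contrast("C4", Condition.H24, Condition.H4),
    Contrast("C5", Condition.R22, Condition.H4),
    Contrast("C6", Condition.R22, Condition.H24),
)

#: Per-contrast raw-p significance cutoffs tuned to ~1% FDR.
DEFAULT_ALPHAS: dict[str, float] = {
    "C1": 0.0005,
    "C2": 0.001,
    "C3": 0.001,
    "C4": 0.0004,
    "C5": 0.0007,
    "C6": 0.0005,
}


@dataclass(frozen=True)
class VariancePrior:
    """Empirical-Bayes hyperparameters: prior df and prior variance."""

    d0: float  # may be math.inf for homogeneous variances; 0 disables shrinkage
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


@dataclass
class ContrastThresholds:
    alpha: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ALPHAS))
    mode: str = "raw_p"  # or "adjusted_p"

    def __post_init__(self) -> None:
        if self.mode not in ("raw_p", "adjusted_p"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        for cid, a in self.alpha.items():
            if not (0 < a < 1):
                raise ValueError(f"alpha for {cid} must be in (0,1), got {a}")


def pooled_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Two-sample ingredients: mean difference, pooled variance, residual df.

    NaNs are dropped (available-case analysis).  Raises ``ValueError``
    when fewer than 2 observed values remain on either side; callers
    flag such proteins as untestable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observed values on each side")
    df = len(x) + len(y) - 2
    ss = np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)
    return float(x.mean() - y.mean()), float(ss / df), df


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma, monotone)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def fit_variance_prior(
    s_g_sq: np.ndarray, df_g: np.ndarray, min_proteins: int = 50
) -> VariancePrior:
    """Estimate (d0, s0_sq) by moment matching of log sample variances.

    Uses the standard closed form: with z = log(s_g^2), e = z -
    digamma(df/2) + log(df/2) has mean log(s0^2) + digamma(d0/2) -
    log(d0/2) and excess variance trigamma(d0/2) beyond the sampling
    term trigamma(df/2); d0 is recovered by trigamma inversion.  Zero
    sample variances are handled by offsetting with a small fraction of
    the positive median (degenerate exact ties in simulated data).
    """
    s_g_sq = np.asarray(s_g_sq, dtype=float)
    df_g = np.asarray(df_g, dtype=float)
    ok = np.isfinite(s_g_sq) & np.isfinite(df_g) & (df_g > 0)
    s_g_sq, df_g = s_g_sq[ok], df_g[ok]
    if len(s_g_sq) < min_proteins:
        raise ValueError(
            f"need >= {min_proteins} testable proteins to fit the prior, "
            f"got {len(s_g_sq)}"
        )
    if np.all(s_g_sq == 0):
        raise ValueError("all sample variances are zero; cannot fit prior")
    if np.ptp(s_g_sq) == 0:
        # exactly constant variances: infinitely concentrated prior
        return VariancePrior(d0=math.inf, s0_sq=float(s_g_sq[0]))
    work = s_g_sq.copy()
    if (work == 0).any():
        work = work + 0.01 * np.median(work[work > 0])
    z = np.log(work)
    e = z - special.digamma(df_g / 2.0) + np.log(df_g / 2.0)
    e_mean = float(np.mean(e))
    n = len(e)
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1))
    excess = e_var - float(np.mean(special.polygamma(1, df_g / 2.0)))
    if excess <= 0:
        return VariancePrior(d0=math.inf, s0_sq=float(np.exp(e_mean)))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def moderated_t(
    log2fc: float,
    s_g_sq: float,
    df_g: float,
    prior: VariancePrior,
    n_x: int,
    n_y: int,
) -> tuple[float, float, float]:
    """Moderated t-statistic, posterior variance and two-sided raw p.

    s_post^2 = (d0*s0^2 + df_g*s_g^2) / (d0 + df_g); the statistic is
    referred to a t distribution with df_g + d0 degrees of freedom.
    d0 = 0 is accepted here and reduces to the ordinary pooled t-test.
    """
    if df_g < 1:
        raise ValueError("df_g must be >= 1")
    d0 = prior.d0
    if math.isinf(d0):
        s_post_sq = prior.s0_sq
        df_total = math.inf
    else:
        s_post_sq = (d0 * prior.s0_sq + df_g * s_g_sq) / (d0 + df_g)
        df_total = df_g + d0
    scale_sq = s_post_sq * (1.0 / n_x + 1.0 / n_y)
    if scale_sq == 0:
        # documented convention for degenerate zero posterior variance
        t_mod = math.inf * np.sign(log2fc) if log2fc != 0 else 0.0
        p_raw = 0.0 if log2fc != 0 else 1.0
        return t_mod, s_post_sq, p_raw
    t_mod = log2fc / math.sqrt(scale_sq)
    if math.isinf(df_total):
        p_raw = 2.0 * float(stats.norm.sf(abs(t_mod)))
    else:
        p_raw = 2.0 * float(stats.t.sf(abs(t_mod), df_total))
    return float(t_mod), float(s_post_sq), min(p_raw, 1.0)


def storey_pi0(p: np.ndarray, lam: float = 0.5) -> float:
    """Storey estimate of the true-null proportion at a single lambda."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return 1.0
    pi0 = np.mean(p > lam) / (1.0 - lam)
    return float(min(max(pi0, 1.0 / len(p)), 1.0))


def adjust_pvalues(
    p_raw: np.ndarray, method: str = "storey_lambda", lam: float = 0.5
) -> tuple[np.ndarray, dict]:
    """Benjamini-Hochberg step-up adjustment, optionally scaled by pi0.

    ``storey_lambda`` multiplies the BH adjusted values by an estimated
    null proportion (the "adapted" BH calibration); ``bh_plain`` forces
    pi0 = 1.  Output is clipped to [p_raw, 1] and monotone in p_raw.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy(), {"pi0_hat": 1.0, "method": method}
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh_plain":
        pi0 = 1.0
    elif method == "storey_lambda":
        pi0 = storey_pi0(p[~np.isnan(p)], lam)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    ok = ~np.isnan(p)
    padj = np.full_like(p, np.nan)
    pv = p[ok]
    n = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]  # step-up
    adj = np.empty(n)
    adj[order] = np.clip(ranked * pi0, 0.0, 1.0)
    adj = np.maximum(adj, pv)  # never below the raw p
    padj[ok] = adj
    return padj, {"pi0_hat": pi0, "method": method}


def call_significance(
    log2fc: np.ndarray,
    p: np.ndarray,
    alpha: float,
    untestable: np.ndarray | None = None,
) -> np.ndarray:
    """Signed calls: sign(log2fc) where p <= alpha (inclusive), else 0."""
    log2fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(p, dtype=float)
    sig = np.where(np.isnan(p), False, p <= alpha)
    signs = np.sign(np.nan_to_num(log2fc)).astype(int)
    call = np.where(sig, signs, 0)
    if untestable is not None:
        call = np.where(untestable, 0, call)
    return call.astype(int)


def run_contrasts(
    m: AbundanceMatrix,
    design: SampleDesign,
    thresholds: ContrastThresholds | None = None,
    adjust_method: str = "storey_lambda",
    prior: VariancePrior | None = None,
) -> pd.DataFrame:
    """Test all six canonical contrasts on a log2 abundance matrix.

    Returns one row per protein x contrast with columns ``accession,
    contrast, log2fc, s_g_sq, df_g, s_post_sq, t_mod, p_raw, p_adj,
    call, untestable``.  The variance prior is fitted separately for
    each contrast.  Proteins with < 2 observed replicates on either side
    of a contrast are kept with ``untestable = True`` and call 0.
    """
    if m.scale != "log2":
        raise ValueError("run_contrasts requires a log2-scale matrix")
    thresholds = thresholds or ContrastThresholds()
    design.require_conditions(
        {c.numerator for c in CONTRASTS} | {c.denominator for c in CONTRASTS}
    )
    m.check_design(design)
    frames = []
    for contrast in CONTRASTS:
        xs = [s for s in design.samples_for(contrast.numerator) if s in m.data.columns]
        ys = [s for s in design.samples_for(contrast.denominator) if s in m.data.columns]
        x = m.data[xs].to_numpy(dtype=float)
        y = m.data[ys].to_numpy(dtype=float)
        n_x = np.sum(~np.isnan(x), axis=1)
        n_y = np.sum(~np.isnan(y), axis=1)
        testable = (n_x >= 2) & (n_y >= 2)

        mean_x = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=1)
        mean_y = np.nanmean(np.where(np.isnan(y), np.nan, y), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ss_x = np.nansum((x - mean_x[:, None]) ** 2, axis=1)
            ss_y = np.nansum((y - mean_y[:, None]) ** 2, axis=1)
        df_g = (n_x + n_y - 2).astype(float)
        log2fc = mean_x - mean_y
        s_g_sq = np.where(testable, (ss_x + ss_y) / np.where(df_g > 0, df_g, 1.0), np.nan)

        c_prior = prior or fit_variance_prior(s_g_sq[testable], df_g[testable])
        d0 = c_prior.d0
        if math.isinf(d0):
            s_post_sq = np.full_like(s_g_sq, c_prior.s0_sq)
            df_total = math.inf
        else:
            s_post_sq = (d0 * c_prior.s0_sq + df_g * s_g_sq) / (d0 + df_g)
            df_total = df_g + d0
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(s_post_sq * (1.0 / n_x + 1.0 / n_y))
            t_mod = log2fc / se
        if math.isinf(d0):
            p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
        else:
            p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
        p_raw = np.where(testable, np.minimum(p_raw, 1.0), np.nan)
        t_mod = np.where(testable, t_mod, np.nan)
        log2fc = np.where(testable, log2fc, np.nan)

        p_adj, calib = adjust_pvalues(p_raw[testable], method=adjust_method)
        p_adj_full = np.full(len(p_raw), np.nan)
        p_adj_full[testable] = p_adj

        p_used = p_raw if thresholds.mode == "raw_p" else p_adj_full
        call = call_significance(
            log2fc, p_used, thresholds.alpha[contrast.id], untestable=~testable
        )
        frames.append(
            pd.DataFrame(
                {
                    "accession": m.data.index,
                    "contrast": contrast.id,
                    "log2fc": log2fc,
                    "s_g_sq": s_g_sq,
                    "df_g": df_g,
                    "s_post_sq": np.where(testable, s_post_sq, np.nan),
                    "t_mod": t_mod,
                    "p_raw": p_raw,
                    "p_adj": p_adj_full,
                    "call": call,
                    "untestable": ~testable,
                    "d0": d0,
                    "s0_sq": c_prior.s0_sq,
                    "pi0_hat": calib["pi0_hat"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def contrast_summary(ct: pd.DataFrame) -> pd.DataFrame:
    """Per-contrast up/down/total significant counts (volcano summary)."""
    rows = []
    for contrast in CONTRASTS:
        sub = ct[ct["contrast"] == contrast.id]
        up = int((sub["call"] == 1).sum())
        down = int((sub["call"] == -1).sum())
        rows.append(
            {
                "contrast": contrast.id,
                "label": contrast.label,
                "up": up,
                "down": down,
                "total": up + down,
            }
        )
    return pd.DataFrame(rows)


def dap_set(ct: pd.DataFrame) -> list[str]:
    """Accessions significant in at least one contrast."""
    hit = ct.loc[ct["call"] != 0, "accession"].unique()
    return sorted(hit)
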