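"""Negative-binomial Wald test for differential peak occupancy.

The model for peak i in sample j is

    y_ij ~ NB(mu_ij, alpha_i),   mu_ij = f_ij * q_i * exp(x_j * beta_i)

where f_ij is the per-peak normalization factor (size factor times copy
ratio), q_i the baseline occupancy, x_j the treat/control indicator and
alpha_i the NB dispersion (Var = mu + alpha * mu^2).  Dispersions are
estimated by per-peak method of moments on factor-normalized counts,
shrunk geometrically halfway toward a robust log-linear mean-dispersion
trend.  beta_i is estimated by Fisher scoring at fixed alpha_i; the Wald
statistic beta/SE(beta) is referred to the standard normal and p-values
are Benjamini–Hochberg adjusted over all tested peaks.

The public surface follows the statsmodels idiom: build a
:class:`NegativeBinomialPeakModel` from counts, factors and a comparison,
call :meth:`fit`, and read estimates off the returned
:class:`DifferentialPeakResults` (or its :meth:`summary`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

LN2 = float(np.log(2.0))
ALPHA_FLOOR = 1e-8
ALPHA_CAP = 10.0
TREND_WEIGHT = 0.5
MAX_ITER = 100
BETA_TOL = 1e-8


@dataclass
class ComparisonSpec:
    """A named two-group contrast: treat vs control sample ids."""

    name: str
    treat_ids: list[str]
    control_ids: list[str]

    def __post_init__(self) -> None:
        if set(self.treat_ids) & set(self.control_ids):
            raise ValueError(f"comparison {self.name}: treat/control overlap")
        if len(self.treat_ids) < 2 or len(self.control_ids) < 2:
            raise ValueError(
                f"comparison {self.name}: need >=2 samples per group"
            )

    def indicator(self, samples: Sequence[str]) -> np.ndarray:
        missing = (set(self.treat_ids) | set(self.control_ids)) - set(samples)
        if missing:
            raise ValueError(f"comparison {self.name}: unknown samples {sorted(missing)}")
        return np.array(
            [s in self.treat_ids for s in samples if s in self.treat_ids or s in self.control_ids],
            dtype=float,
        )

    def column_index(self, samples: Sequence[str]) -> np.ndarray:
        wanted = set(self.treat_ids) | set(self.control_ids)
        missing = wanted - set(samples)
        if missing:
            raise ValueError(f"comparison {self.name}: unknown samples {sorted(missing)}")
        return np.array([i for i, s in enumerate(samples) if s in wanted], dtype=int)


@dataclass
class DispersionEstimate:
    """Per-peak NB dispersions: raw moments, fitted trend, shrunk final."""

    alpha: np.ndarray
    alpha_moments: np.ndarray
    alpha_trend: np.ndarray
    stage: str = "shrunk"


def _pooled_moments(normed: np.ndarray, group: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Overall mean and pooled within-group variance of normalized counts."""
    base_mean = normed.mean(axis=1)
    ssq = np.zeros(normed.shape[0])
    dof = normed.shape[1] - 2
    for g in (0.0, 1.0):
        cols = normed[:, group == g]
        ssq += ((cols - cols.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = ssq / max(dof, 1)
    return base_mean, pooled_var


def estimate_dispersions(
    counts: np.ndarray,
    factors: np.ndarray,
    group: np.ndarray,
    floor: float = ALPHA_FLOOR,
    cap: float = ALPHA_CAP,
    trend_weight: float = TREND_WEIGHT,
) -> DispersionEstimate:
    """Moment dispersions shrunk toward a robust log-linear trend.

    alpha_mom = max((pooled within-group variance - mean) / mean^2, floor);
    the trend is a Huber-robust regression of log(alpha_mom) on
    log(base mean) over peaks above the floor; the final dispersion is the
    geometric interpolation exp(w*log trend + (1-w)*log alpha_mom).
    """
    group = np.asarray(group, dtype=float)
    for g in (0.0, 1.0):
        if (group == g).sum() < 2:
            raise ValueError("need >=2 samples in each group to estimate dispersion")
    normed = np.asarray(counts, dtype=float) / np.asarray(factors, dtype=float)
    base_mean, pooled_var = _pooled_moments(normed, group)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (pooled_var - base_mean) / base_mean**2
    raw = np.where(base_mean > 0, raw, floor)
    alpha_mom = np.clip(raw, floor, cap)

    # the moment estimate scales with a chi-square on dof degrees of freedom,
    # so log(alpha_mom) is median-biased low; debias on the log scale before
    # the robust trend fit and the geometric combination
    from scipy.special import digamma

    dof = max(normed.shape[1] - 2, 1)
    debias = np.log(dof / 2.0) - digamma(dof / 2.0)
    alpha_deb = np.clip(alpha_mom * np.exp(debias), floor, cap)

    informative = (alpha_mom > floor * 1.01) & (base_mean > 0)
    if informative.sum() >= 10:
        import statsmodels.api as sm

        x = sm.add_constant(np.log(base_mean[informative]))
        rlm = sm.RLM(np.log(alpha_deb[informative]), x, M=sm.robust.norms.HuberT())
        res = rlm.fit()
        with np.errstate(divide="ignore"):
            logbm = np.log(np.where(base_mean > 0, base_mean, 1.0))
        trend = np.exp(res.params[0] + res.params[1] * logbm)
    else:
        # too few informative peaks for a trend: flat at their geometric mean
        pool = alpha_deb[informative] if informative.any() else alpha_deb
        trend = np.full_like(alpha_mom, np.exp(np.mean(np.log(pool))))
    alpha_trend = np.clip(trend, floor, cap)
    alpha = np.exp(
        trend_weight * np.log(alpha_trend) + (1 - trend_weight) * np.log(alpha_deb)
    )
    # a floored moment estimate (sub-Poisson empirical variance) carries no
    # information about the dispersion; such peaks take the trend outright
    # rather than being dragged geometrically toward zero
    alpha = np.where(informative, alpha, alpha_trend)
    return DispersionEstimate(
        alpha=np.clip(alpha, floor, cap),
        alpha_moments=alpha_mom,
        alpha_trend=alpha_trend,
    )


def _fisher_scoring(
    y: np.ndarray, f: np.ndarray, x: np.ndarray, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-parameter NB GLM fit over all peaks at once.

    Returns (beta, se, converged, mu_hat) with beta the natural-log group
    effect.  Uses expected-information Newton steps on (log q, beta).
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    alpha = np.asarray(alpha, dtype=float)[:, None]
    treat = x == 1.0
    eps = 1e-3
    mc = (y[:, ~treat] / f[:, ~treat]).mean(axis=1)
    mt = (y[:, treat] / f[:, treat]).mean(axis=1)
    b0 = np.log(mc + eps)
    b1 = np.log(mt + eps) - np.log(mc + eps)
    active = np.ones(y.shape[0], dtype=bool)
    converged = np.zeros(y.shape[0], dtype=bool)
    xrow = x[None, :]
    for _ in range(MAX_ITER):
        if not active.any():
            break
        mu = f[active] * np.exp(np.clip(b0[active, None] + b1[active, None] * xrow, -700, 700))
        a = alpha[active] if alpha.shape[0] > 1 else alpha
        denom = 1.0 + a * mu
        r = (y[active] - mu) / denom
        w = mu / denom
        s0 = r.sum(axis=1)
        s1 = (r * xrow).sum(axis=1)
        i_t = (w * xrow).sum(axis=1)
        i_all = w.sum(axis=1)
        i_c = i_all - i_t
        det = np.maximum(i_t * i_c, 1e-300)
        d0 = (i_t * s0 - i_t * s1) / det  # = (I11*s0 - I01*s1)/det with I11=I01=i_t
        d1 = (i_all * s1 - i_t * s0) / det
        d0 = np.clip(d0, -5.0, 5.0)
        d1 = np.clip(d1, -5.0, 5.0)
        idx = np.flatnonzero(active)
        b0[idx] = np.clip(b0[idx] + d0, -50.0, 50.0)
        b1[idx] = np.clip(b1[idx] + d1, -25.0, 25.0)
        done = (np.abs(d0) < BETA_TOL) & (np.abs(d1) < BETA_TOL)
        converged[idx[done]] = True
        active[idx[done]] = False
    mu_hat = f * np.exp(np.clip(b0[:, None] + b1[:, None] * xrow, -700, 700))
    denom = 1.0 + alpha * mu_hat
    w = mu_hat / denom
    i_t = (w * xrow).sum(axis=1)
    i_c = w.sum(axis=1) - i_t
    with np.errstate(divide="ignore"):
        var_b1 = 1.0 / np.maximum(i_t, 1e-300) + 1.0 / np.maximum(i_c, 1e-300)
    return b1, np.sqrt(var_b1), converged, mu_hat


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (NaNs passed through)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


class NegativeBinomialPeakModel:
    """NB GLM for a two-group differential peak comparison.

    Parameters
    ----------
    counts
        Integer count matrix (peaks x samples) or a
        :class:`peakdiff.counting.CountMatrix`.
    factors
        Per-peak normalization factors (peaks x samples), strictly positive.
        Typically ``size_factor_j`` broadcast per row, times copy ratios.
    spec
        :class:`ComparisonSpec` naming treat and control samples, or a plain
        0/1 indicator array when ``counts`` is a bare matrix.
    """

    def __init__(self, counts, factors, spec, samples: Sequence[str] | None = None,
                 peak_table: pd.DataFrame | None = None):
        raw = getattr(counts, "counts", counts)
        if samples is None:
            samples = list(getattr(counts, "samples", [f"s{j}" for j in range(raw.shape[1])]))
        if peak_table is None:
            peaks = getattr(counts, "peaks", None)
            peak_table = peaks.to_frame() if peaks is not None else None
        factors = np.asarray(factors, dtype=float)
        if factors.ndim == 1:
            factors = np.tile(factors, (raw.shape[0], 1))
        if np.any(factors <= 0):
            raise ValueError("normalization factors must be strictly positive")
        if isinstance(spec, ComparisonSpec):
            cols = spec.column_index(samples)
            self.group = np.array(
                [1.0 if samples[i] in spec.treat_ids else 0.0 for i in cols]
            )
            self.counts = np.asarray(raw, dtype=float)[:, cols]
            self.factors = factors[:, cols]
            self.samples = [samples[i] for i in cols]
            self.name = spec.name
        else:
            self.group = np.asarray(spec, dtype=float)
            self.counts = np.asarray(raw, dtype=float)
            self.factors = factors
            self.samples = list(samples)
            self.name = "comparison"
        for g in (0.0, 1.0):
            if (self.group == g).sum() < 2:
                raise ValueError("each group needs >=2 samples")
        self.peak_table = peak_table

    def fit(self, dispersions: DispersionEstimate | None = None) -> "DifferentialPeakResults":
        tested = self.counts.sum(axis=1) > 0
        if dispersions is None:
            dispersions = estimate_dispersions(self.counts, self.factors, self.group)
        n = self.counts.shape[0]
        log2_fc = np.full(n, np.nan)
        se = np.full(n, np.nan)
        wald = np.full(n, np.nan)
        p = np.full(n, np.nan)
        converged = np.zeros(n, dtype=bool)
        base_mean = (self.counts / self.factors).mean(axis=1)
        if tested.any():
            b1, se_b, conv, _ = _fisher_scoring(
                self.counts[tested],
                self.factors[tested],
                self.group,
                dispersions.alpha[tested],
            )
            z = b1 / se_b
            pt = 2.0 * stats.norm.sf(np.abs(z))
            pt = np.where(conv, pt, 1.0)  # non-converged peaks reported at p=1
            log2_fc[tested] = b1 / LN2
            se[tested] = se_b / LN2
            wald[tested] = z
            p[tested] = pt
            converged[tested] = conv
        padj = bh_adjust(p)
        return DifferentialPeakResults(
            model=self,
            base_mean=base_mean,
            log2_fc=log2_fc,
            se=se,
            wald=wald,
            p=p,
            padj=padj,
            tested=tested,
            converged=converged,
            dispersions=dispersions,
        )


@dataclass
class DifferentialPeakResults:
    """Per-peak NB Wald statistics for one two-group comparison."""

    model: NegativeBinomialPeakModel
    base_mean: np.ndarray
    log2_fc: np.ndarray
    se: np.ndarray
    wald: np.ndarray
    p: np.ndarray
    padj: np.ndarray
    tested: np.ndarray
    converged: np.ndarray
    dispersions: DispersionEstimate

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "base_mean": self.base_mean,
            "log2_fc": self.log2_fc,
            "se": self.se,
            "wald": self.wald,
            "p": self.p,
            "padj": self.padj,
        }
        if self.model.peak_table is not None:
            df = self.model.peak_table.copy().reset_index(drop=True)
            for k, v in cols.items():
                df[k] = v
            return df
        return pd.DataFrame(cols)

    def summary_table(
        self,
        padj_cutoffs: tuple[float, float] = (0.05, 0.01),
        fc_cutoffs: tuple[float, float] = (1.5, 2.0),
    ) -> pd.DataFrame:
        """Dual-cutoff grid: up/down peak counts per (padj, FC) cell."""
        rows = []
        for pc in padj_cutoffs:
            for fc in fc_cutoffs:
                lfc = np.log2(fc)
                ok = np.isfinite(self.padj) & np.isfinite(self.log2_fc)
                up = int(np.sum(ok & (self.padj <= pc) & (self.log2_fc >= lfc)))
                down = int(np.sum(ok & (self.padj <= pc) & (self.log2_fc <= -lfc)))
                rows.append({"padj_cutoff": pc, "fc_cutoff": fc, "up": up, "down": down})
        return pd.DataFrame(rows)

    def ma_data(self, padj_cutoff: float = 0.05) -> pd.DataFrame:
        """Per-peak (base_mean, log2_fc, significant) table for an MA plot."""
        sig = np.isfinite(self.padj) & (self.padj <= padj_cutoff)
        return pd.DataFrame(
            {
                "base_mean": self.base_mean,
                "log2_fc": self.log2_fc,
                "significant": sig,
            }
        )

    def summary(self) -> str:
        n_tested = int(self.tested.sum())
        n_sig = int(np.nansum(self.padj <= 0.05))
        lines = [
            f"NB Wald differential peak test: {self.model.name}",
            f"  samples: {len(self.model.samples)} "
            f"(treat {int(self.model.group.sum())}, "
            f"control {int((1 - self.model.group).sum())})",
            f"  peaks tested: {n_tested} / {len(self.tested)}",
            f"  median dispersion: {np.median(self.dispersions.alpha[self.tested]):.4g}",
            f"  peaks at padj <= 0.05: {n_sig}",
        ]
        lines.append(self.summary_table().to_string(index=False))
        return "\n".join(lines)


def nb_wald_test(counts, factors, spec, dispersions=None, samples=None) -> DifferentialPeakResults:
    """Functional wrapper: build the model and fit it in one call."""
    model = NegativeBinomialPeakModel(counts, factors, spec, samples=samples)
    return model.fit(dispersions=dispersions)


def summary_table(results: DifferentialPeakResults, padj_cutoffs=(0.05, 0.01),
                  fc_cutoffs=(1.5, 2.0)) -> pd.DataFrame:
    return results.summary_table(padj_cutoffs=padj_cutoffs, fc_cutoffs=fc_cutoffs)


def ma_data(results: DifferentialPeakResults, padj_cutoff: float = 0.05) -> pd.DataFrame:
    return results.ma_data(padj_cutoff=padj_cutoff)
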