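"""Bootstrap uncertainty quantification and affinity-ranking metrics.

Uncertainties follow a nonparametric bootstrap: the per-replica ΔG averages
are resampled with replacement (5000 times by default), the statistic of
interest is recomputed on each resample, and the standard deviation of the
bootstrap distribution is quoted as the error; 95% confidence intervals are
the 2.5/97.5 percentiles of the sorted distribution. For ranking metrics
the resampling unit is the ligand-level (calculated, experimental) pair.

Metrics:

* cMUE — mean unsigned error after removing the mean signed (systematic)
  offset; raw MMPBSA values carry a large constant offset from experiment,
  so ranking claims should not be charged for it.
* r — Pearson correlation; r_s — Spearman rank correlation (mid-rank ties).
* PI — predictive index: pairwise sign-agreement between predicted and
  experimental affinity differences, weighted by |ΔΔG_expt|
  (Pearlman–Charifson definition).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .model import ExperimentalRecord, ValidationError


@dataclass(frozen=True)
class BootstrapSpec:
    """Resampling settings: B resamples, CI percentiles, RNG seed."""

    resamples: int = 5000
    ci: tuple[float, float] = (2.5, 97.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resamples < 1:
            raise ValidationError("bootstrap needs at least one resample")
        if not self.ci[0] < self.ci[1]:
            raise ValidationError("CI percentiles must be ordered")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class MetricResult:
    value: float
    se: float
    ci: tuple[float, float]


@dataclass
class RankingMetrics:
    """The four protocol-performance metrics with bootstrap uncertainties."""

    cmue: MetricResult
    pi: MetricResult
    r: MetricResult
    r_s: MetricResult
    n_ligands: int
    redraws: int = 0  # degenerate correlation resamples that were redrawn

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {"n_ligands": self.n_ligands}
        for name in ("cmue", "pi", "r", "r_s"):
            m: MetricResult = getattr(self, name)
            out[name] = m.value
            out[f"{name}_err"] = m.se
            out[f"{name}_ci_low"], out[f"{name}_ci_high"] = m.ci
        return out


# ---------------------------------------------------------------------------
# Elementary metrics


def cmue(calc: Sequence[float], expt: Sequence[float]) -> float:
    """Mean unsigned error corrected for the mean signed (systematic) error."""
    calc = np.asarray(calc, float)
    expt = np.asarray(expt, float)
    if calc.shape != expt.shape or calc.size == 0:
        raise ValidationError("cmue needs aligned, non-empty inputs")
    signed = calc - expt
    return float(np.mean(np.abs(signed - signed.mean())))


def predictive_index(calc: Sequence[float], expt: Sequence[float]) -> float:
    """PI = Σ_{j>i} w_ij·c_ij / Σ w_ij, w_ij = |ΔΔG_expt|, c_ij = sign agreement.

    c_ij is +1 when the calculated difference has the same sign as the
    experimental one, −1 when opposite, and 0 when the calculated
    difference is exactly zero.
    """
    calc = np.asarray(calc, float)
    expt = np.asarray(expt, float)
    if calc.size < 2:
        raise ValidationError("predictive index needs at least two ligands")
    de = expt[None, :] - expt[:, None]
    dc = calc[None, :] - calc[:, None]
    iu = np.triu_indices(calc.size, k=1)
    w = np.abs(de[iu])
    if np.all(w == 0):
        raise ValidationError("all experimental values equal; PI undefined")
    c = np.sign(de[iu]) * np.sign(dc[iu])
    c[dc[iu] == 0] = 0.0
    return float(np.sum(w * c) / np.sum(w))


def pearson_r(calc: Sequence[float], expt: Sequence[float]) -> float:
    return float(sps.pearsonr(calc, expt).statistic)


def spearman_rs(calc: Sequence[float], expt: Sequence[float]) -> float:
    return float(sps.spearmanr(calc, expt).statistic)


METRICS: dict[str, Callable[[Sequence[float], Sequence[float]], float]] = {
    "cmue": cmue, "pi": predictive_index, "r": pearson_r, "r_s": spearman_rs,
}


def pic50_to_dg(pic50: float,
                constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """ΔG = −k_B·T·ln(10)·pIC50 (kcal/mol), the IC50→affinity conversion."""
    if not np.isfinite(pic50):
        raise ValidationError("pIC50 must be finite")
    return float(-constants.kT * np.log(10.0) * pic50)


def experimental_dg(record: ExperimentalRecord,
                    constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """ΔG_expt, converting from pIC50 when no direct value is given."""
    if record.dG_expt is not None:
        return float(record.dG_expt)
    return pic50_to_dg(record.pIC50, constants)


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_se(values: Sequence[float], spec: BootstrapSpec = BootstrapSpec(),
                 ) -> tuple[float, tuple[float, float]]:
    """SE and percentile CI of the mean by resampling with replacement."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValidationError("bootstrap_se needs a non-empty sample")
    rng = spec.rng()
    idx = rng.integers(0, values.size, size=(spec.resamples, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, spec.ci)
    return float(means.std(ddof=0)), (float(lo), float(hi))


def bootstrap_metric(calc: Sequence[float], expt: Sequence[float], metric: str,
                     spec: BootstrapSpec = BootstrapSpec(),
                     rng: np.random.Generator | None = None,
                     ) -> tuple[MetricResult, int]:
    """Bootstrap one ranking metric over ligand pairs.

    Resamples with zero variance in either margin (or all-equal
    experimental weights for PI) cannot be scored and are redrawn; the
    redraw count is returned so an effective-B audit is possible.
    """
    calc = np.asarray(calc, float)
    expt = np.asarray(expt, float)
    n = calc.size
    if n < 3:
        raise ValidationError("bootstrap of ranking metrics needs >= 3 ligands")
    fn = METRICS[metric]
    point = fn(calc, expt)
    rng = spec.rng() if rng is None else rng
    needs_spread = metric in ("pi", "r", "r_s")
    out = np.empty(spec.resamples)
    redraws = 0
    filled = 0
    while filled < spec.resamples:
        idx = rng.integers(0, n, size=n)
        c, e = calc[idx], expt[idx]
        if needs_spread and (np.ptp(e) == 0 or np.ptp(c) == 0):
            redraws += 1
            if redraws > 1000 * spec.resamples:  # pathological degenerate input
                raise ValidationError("bootstrap cannot find non-degenerate resamples")
            continue
        out[filled] = fn(c, e)
        filled += 1
    lo, hi = np.percentile(out, spec.ci)
    return MetricResult(point, float(out.std(ddof=0)), (float(lo), float(hi))), redraws


def bootstrap_correlation(pairs: Sequence[tuple[float, float]], metric: str = "r_s",
                          spec: BootstrapSpec = BootstrapSpec(),
                          ) -> tuple[float, float, tuple[float, float]]:
    """Convenience wrapper: (value, SE, CI) for a correlation over pairs."""
    arr = np.asarray(pairs, float)
    res, _ = bootstrap_metric(arr[:, 0], arr[:, 1], metric, spec)
    return res.value, res.se, res.ci


# ---------------------------------------------------------------------------
# Protocol evaluation


def evaluate_protocol(calc_by_ligand: dict[str, float] | pd.Series,
                      experimental: Sequence[ExperimentalRecord],
                      spec: BootstrapSpec = BootstrapSpec(),
                      constants: PhysicalConstants = DEFAULT_CONSTANTS,
                      ) -> RankingMetrics:
    """All four metrics with bootstrap errors, on ligand-level mean ΔG values."""
    calc_map = dict(calc_by_ligand)
    expt_map = {r.ligand_id: experimental_dg(r, constants) for r in experimental}
    unmatched = sorted(set(calc_map) - set(expt_map))
    if unmatched:
        raise ValidationError(
            f"calculated ligand(s) missing from the experimental table: {unmatched}")
    matched = sorted(set(calc_map) & set(expt_map))
    if len(matched) < 3:
        raise ValidationError(f"need >= 3 matched ligands, have {len(matched)}")
    calc = np.array([calc_map[k] for k in matched])
    expt = np.array([expt_map[k] for k in matched])
    rng = spec.rng()
    results = {}
    total_redraws = 0
    for name in ("cmue", "pi", "r", "r_s"):
        res, redraws = bootstrap_metric(calc, expt, name, spec, rng=rng)
        results[name] = res
        total_redraws += redraws
    return RankingMetrics(cmue=results["cmue"], pi=results["pi"],
                          r=results["r"], r_s=results["r_s"],
                          n_ligands=len(matched), redraws=total_redraws)
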