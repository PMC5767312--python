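"""qPCR relative quantification used to cross-validate the arrays.

The quantification stack:

* **Efficiency estimation** from raw amplification curves, in the
  window-of-linearity style: subtract a fixed baseline (mean fluorescence
  of cycles 1–5), regress log10 fluorescence on cycle number over every
  contiguous window of 4–6 cycles in the exponential phase, keep the
  window with maximal R²; E = 10^slope. Per-amplicon E is the mean of
  per-well estimates whose window R² ≥ 0.99.
* **Pfaffl ratio** R = E_target^ΔCt(target) / E_ref^ΔCt(ref), where
  ΔCt = mean Ct(control) − mean Ct(treated) per amplicon. With both
  efficiencies equal to 2 this reduces to the classic 2^ΔΔCt.
* **Randomization significance** in the fixed-reallocation style:
  treatment labels of paired (target, reference) observations are
  reallocated without replacement, the ratio recomputed, and the
  two-sided p taken from the extremeness of |log R|. When the number of
  distinct reallocations is at most 10 000 the test enumerates all of
  them exactly; otherwise it samples with a seeded generator.
* **(40 − dCt)** display value for comparing expression levels between
  control samples: 40 − (Ct_target − Ct_reference).
* **Platform concordance**: Spearman rank correlation (average ranks for
  ties) between array and qPCR log2 fold changes, with a seeded
  permutation p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


class EfficiencyError(ValueError):
    """Raised when a curve has no usable exponential phase."""


@dataclass(frozen=True)
class RatioResult:
    ratio: float
    p: float
    n_permutations: int
    exhaustive: bool
    seed: int | None = None


@dataclass(frozen=True)
class ConcordanceResult:
    rho: float
    p: float
    n: int


def estimate_efficiency(
    fluorescence: np.ndarray,
    window_min: int = 4,
    window_max: int = 6,
    baseline_cycles: int = 5,
    r2_min: float = 0.98,
) -> float:
    """Per-well amplification efficiency from a raw curve.

    ``fluorescence`` is indexed by cycle (cycle 1 first). Returns E in
    (1, 2.5]; warns outside (1, 2.1].
    """
    f = np.asarray(fluorescence, dtype=float)
    if f.size < 10:
        raise EfficiencyError(f"curve too short ({f.size} cycles; need ≥ 10)")
    if not np.isfinite(f).all():
        raise EfficiencyError("non-finite fluorescence")
    baseline = f[:baseline_cycles].mean()
    corrected = f - baseline
    positive = corrected > 0

    best = None  # (r2, slope)
    for w in range(window_min, window_max + 1):
        for start in range(0, f.size - w + 1):
            seg = corrected[start : start + w]
            if not positive[start : start + w].all():
                continue
            if not np.all(np.diff(seg) > 0):
                continue  # exponential phase is strictly increasing
            y = np.log10(seg)
            x = np.arange(start, start + w, dtype=float)
            slope, _, r, _, _ = stats.linregress(x, y)
            if slope <= 0:
                continue
            r2 = r * r
            if best is None or r2 > best[0]:
                best = (r2, slope)
    if best is None or best[0] < r2_min:
        raise EfficiencyError("no qualifying window of linearity found")
    e = 10.0 ** best[1]
    if e > 2.5:
        e = 2.5
    if not 1.0 < e <= 2.1:
        import warnings

        warnings.warn(f"estimated efficiency {e:.3f} outside (1, 2.1]", stacklevel=2)
    if e <= 1.0:
        raise EfficiencyError(f"estimated efficiency {e:.3f} not above 1")
    return float(e)


def amplicon_efficiency(curves: list[np.ndarray], r2_keep: float = 0.99, **kwargs) -> float:
    """Mean of per-well estimates whose best window reaches R² ≥ r2_keep."""
    estimates = []
    for curve in curves:
        try:
            estimates.append(estimate_efficiency(curve, r2_min=r2_keep, **kwargs))
        except EfficiencyError:
            continue
    if not estimates:
        raise EfficiencyError("no well produced a qualifying efficiency estimate")
    return float(np.mean(estimates))


def pfaffl_ratio(e_target: float, dct_target: float, e_ref: float, dct_ref: float) -> float:
    """Efficiency-corrected relative expression.

    R = E_target^ΔCt(target) / E_ref^ΔCt(ref), ΔCt = mean Ct(control) −
    mean Ct(treated).
    """
    for name, e in (("target", e_target), ("reference", e_ref)):
        if not 1.0 < e <= 2.5:
            raise ValueError(f"{name} efficiency must be in (1, 2.5], got {e}")
    return float(e_target**dct_target / e_ref**dct_ref)


def randomization_test(
    control_target: np.ndarray,
    control_ref: np.ndarray,
    treated_target: np.ndarray,
    treated_ref: np.ndarray,
    e_target: float = 2.0,
    e_ref: float = 2.0,
    n_perm: int = 2000,
    seed: int | None = None,
    exhaustive_limit: int = 10_000,
) -> RatioResult:
    """Fixed-reallocation randomization test of the Pfaffl ratio.

    Observations are paired (target Ct, reference Ct) per sample. The
    observed R comes from group-mean ΔCts; each reallocation reassigns
    which samples count as control, keeping group sizes. Two-sided p is
    the extremeness proportion of |log R*|; with sampling it is
    (1 + #more-extreme) / (1 + n_perm).
    """
    ct, cr = np.asarray(control_target, float), np.asarray(control_ref, float)
    tt, tr = np.asarray(treated_target, float), np.asarray(treated_ref, float)
    if len(ct) != len(cr) or len(tt) != len(tr):
        raise ValueError("target and reference Ct vectors must pair up within groups")
    n1, n2 = len(ct), len(tt)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need ≥ 2 observations per group, got {n1} and {n2}")
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")

    target = np.concatenate([ct, tt])
    ref = np.concatenate([cr, tr])
    total = n1 + n2

    def ratio_for(control_idx: np.ndarray) -> float:
        mask = np.zeros(total, dtype=bool)
        mask[control_idx] = True
        dct_t = target[mask].mean() - target[~mask].mean()
        dct_r = ref[mask].mean() - ref[~mask].mean()
        return pfaffl_ratio(e_target, dct_t, e_ref, dct_r)

    observed = ratio_for(np.arange(n1))
    obs_stat = abs(math.log(observed))

    n_distinct = math.comb(total, n1)
    if n_distinct <= exhaustive_limit:
        stats_ = [
            abs(math.log(ratio_for(np.array(idx))))
            for idx in combinations(range(total), n1)
        ]
        more_extreme = sum(s >= obs_stat - 1e-12 for s in stats_)
        return RatioResult(
            ratio=observed,
            p=more_extreme / n_distinct,
            n_permutations=n_distinct,
            exhaustive=True,
            seed=seed,
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.choice(total, size=n1, replace=False)
        if abs(math.log(ratio_for(idx))) >= obs_stat - 1e-12:
            count += 1
    return RatioResult(
        ratio=observed,
        p=(1 + count) / (1 + n_perm),
        n_permutations=n_perm,
        exhaustive=False,
        seed=seed,
    )


def plate_fold_changes(
    wells: pd.DataFrame,
    reference: str,
    efficiencies: Mapping[str, float] | None = None,
    assumed_e: float = 2.0,
) -> pd.DataFrame:
    """Per-amplicon Pfaffl fold changes (drought vs control) for a plate.

    ``wells`` needs columns amplicon, condition, Ct. Efficiencies default
    to ``assumed_e`` for amplicons missing from ``efficiencies``.
    Returns a DataFrame indexed by amplicon with ratio and log2_ratio.
    """
    efficiencies = dict(efficiencies or {})
    ref = wells[wells["amplicon"] == reference]
    if ref.empty:
        raise ValueError(f"reference amplicon {reference!r} not on plate")

    def dct(group: pd.DataFrame) -> float:
        return (
            group.loc[group["condition"] == "control", "Ct"].mean()
            - group.loc[group["condition"] == "drought", "Ct"].mean()
        )

    dct_ref = dct(ref)
    e_ref = efficiencies.get(reference, assumed_e)
    rows = {}
    for amplicon, group in wells.groupby("amplicon"):
        if amplicon == reference:
            continue
        e = efficiencies.get(amplicon, assumed_e)
        ratio = pfaffl_ratio(e, dct(group), e_ref, dct_ref)
        rows[amplicon] = {"ratio": ratio, "log2_ratio": math.log2(ratio)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "amplicon"
    return out


def relative_expression_40_minus_dct(ct_target: float, ct_reference: float) -> float:
    """Display value 40 − dCt, dCt = Ct(target) − Ct(reference)."""
    if ct_target <= 0 or ct_reference <= 0:
        raise ValueError("Ct values must be positive")
    return 40.0 - (ct_target - ct_reference)


def platform_concordance(
    log2fc_array: pd.Series | np.ndarray,
    log2fc_qpcr: pd.Series | np.ndarray,
    n_perm: int = 9999,
    seed: int | None = 0,
) -> ConcordanceResult:
    """Spearman concordance between array and qPCR log2 fold changes.

    Pairs on shared index when both inputs are Series. Ties get average
    ranks; p is a seeded permutation value on |rho|.
    """
    if isinstance(log2fc_array, pd.Series) and isinstance(log2fc_qpcr, pd.Series):
        shared = log2fc_array.index.intersection(log2fc_qpcr.index)
        a = log2fc_array.loc[shared].to_numpy(float)
        b = log2fc_qpcr.loc[shared].to_numpy(float)
    else:
        a = np.asarray(log2fc_array, float)
        b = np.asarray(log2fc_qpcr, float)
        if len(a) != len(b):
            raise ValueError("fold-change vectors must have equal length")
    n = len(a)
    if n < 3:
        raise ValueError(f"need ≥ 3 shared genes, got {n}")
    rho = float(stats.spearmanr(a, b).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_rho = stats.spearmanr(a, rng.permutation(b)).statistic
        if abs(perm_rho) >= abs(rho) - 1e-12:
            count += 1
    return ConcordanceResult(rho=rho, p=(1 + count) / (1 + n_perm), n=n)
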