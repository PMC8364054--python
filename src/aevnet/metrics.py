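"""CASF-style evaluation: scoring, ranking, docking, and screening power.

Conventions (several are under-specified in the benchmark literature and
frozen here):

* Kendall's correlation is the tie-corrected tau-b.
* The predictive index uses weights ``w_ij = |y_j - y_i|`` and per-pair
  sign agreement of predicted vs experimental differences (+1 / -1, 0 when
  the predicted difference is exactly zero).
* "Top alpha%" cuts use the ceiling: the best ``ceil(alpha * N)`` scored
  candidates.
* Bootstrap intervals are seeded percentile intervals over paired
  resamples; a resample on which the metric is undefined (e.g. constant
  vector for a correlation) is redrawn.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ScoredSet",
    "DecoySet",
    "ScreeningSet",
    "MetricsReport",
    "scoring_power",
    "predictive_index",
    "ranking_power",
    "docking_power",
    "screening_power",
    "bootstrap_ci",
]


@dataclass
class ScoredSet:
    ids: list[str]
    y: np.ndarray  # experimental pK
    yhat: np.ndarray  # predicted pK
    class_of: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        self.yhat = np.asarray(self.yhat, dtype=np.float64)
        n = len(self.ids)
        if n < 2 or self.y.shape != (n,) or self.yhat.shape != (n,):
            raise ValueError("ids, y, yhat must be aligned with length >= 2")
        if self.class_of is not None and len(self.class_of) != n:
            raise ValueError("class_of length mismatch")

    def subset(self, idx) -> "ScoredSet":
        idx = np.asarray(idx)
        return ScoredSet(
            [self.ids[k] for k in idx], self.y[idx], self.yhat[idx],
            [self.class_of[k] for k in idx] if self.class_of is not None else None,
        )


@dataclass
class DecoySet:
    """Scored poses of one target: (pose_id, rmsd to native, score in pK)."""

    target_id: str
    poses: list[tuple[str, float, float]]


@dataclass
class ScreeningSet:
    """Scored candidate ligands of one target."""

    target_id: str
    candidates: list[tuple[str, float, bool, bool]]  # (ligand_id, score, is_true_binder, is_best_binder)


@dataclass
class MetricsReport:
    """Point estimates with optional (lo, hi) bootstrap intervals."""

    metrics: dict = field(default_factory=dict)  # name -> {"value", "ci": (lo, hi)}
    per_class: dict = field(default_factory=dict)

    def add(self, name: str, value: float, ci: Optional[tuple] = None) -> None:
        if ci is not None and not (ci[0] <= value <= ci[1] or
                                   math.isclose(ci[0], value) or math.isclose(ci[1], value)):
            warnings.warn(f"{name}: point estimate {value} outside CI {ci}")
        self.metrics[name] = {"value": value, "ci": list(ci) if ci else None}

    def to_json(self, path=None) -> str:
        payload = {"metrics": self.metrics, "per_class": self.per_class}
        s = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["metric", "value", "ci_lo", "ci_hi"])
            for name, rec in self.metrics.items():
                lo, hi = rec["ci"] if rec["ci"] else ("", "")
                w.writerow([name, rec["value"], lo, hi])


# ---------------------------------------------------------------------------
# Scoring power


def pearson_r(y: np.ndarray, yhat: np.ndarray) -> float:
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValueError("Pearson r undefined for a constant vector")
    yc = y - y.mean()
    pc = yhat - yhat.mean()
    return float(np.sum(pc * yc) / math.sqrt(np.sum(pc**2) * np.sum(yc**2)))


def scoring_power(s: ScoredSet) -> tuple[float, float]:
    """(Pearson r, RMSE in pK units) between predictions and experiment."""
    rmse = float(np.sqrt(np.mean((s.yhat - s.y) ** 2)))
    return pearson_r(s.y, s.yhat), rmse


# ---------------------------------------------------------------------------
# Ranking power


def predictive_index(y: np.ndarray, yhat: np.ndarray) -> float:
    """Weighted pairwise concordance with weights |y_j - y_i|."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    n = y.size
    if n < 2:
        raise ValueError("need >= 2 items")
    i, j = np.triu_indices(n, k=1)
    w = np.abs(y[j] - y[i])
    c = np.sign(yhat[j] - yhat[i]) * np.sign(y[j] - y[i])
    wsum = w.sum()
    if wsum == 0:
        raise ValueError("predictive index undefined: all y equal")
    return float(np.sum(w * c) / wsum)


def ranking_power(s: ScoredSet) -> tuple[float, float, float]:
    """Per-class Spearman, Kendall tau-b, and PI, averaged over classes.

    Classes with fewer than two members are excluded with a warning.
    """
    if s.class_of is None:
        raise ValueError("ranking_power requires class labels")
    classes: dict[str, list[int]] = {}
    for k, c in enumerate(s.class_of):
        classes.setdefault(c, []).append(k)
    rhos, taus, pis = [], [], []
    for c, idx in classes.items():
        if len(idx) < 2:
            warnings.warn(f"class {c!r} has a single member; excluded from ranking")
            continue
        y, yhat = s.y[idx], s.yhat[idx]
        rhos.append(float(stats.spearmanr(y, yhat).statistic))
        taus.append(float(stats.kendalltau(y, yhat).statistic))
        pis.append(predictive_index(y, yhat))
    if not rhos:
        raise ValueError("no class with >= 2 members")
    return float(np.mean(rhos)), float(np.mean(taus)), float(np.mean(pis))


# ---------------------------------------------------------------------------
# Docking power


def _ranked_poses(poses):
    """Poses by decreasing score; ties broken by pose_id (stable, documented)."""
    return sorted(poses, key=lambda p: (-p[2], p[0]))


def docking_power(sets: Sequence[DecoySet], rmsd_cut: float = 2.0,
                  top_ks: Sequence[int] = (1, 2, 3)) -> dict[int, float]:
    """Percentage of targets with a pose at rmsd <= cut among the top-k scored."""
    if not sets:
        raise ValueError("no decoy sets")
    for ds in sets:
        if len(ds.poses) < 3:
            raise ValueError(f"target {ds.target_id}: fewer than 3 poses")
        if not all(np.isfinite(p[2]) for p in ds.poses):
            raise ValueError(f"target {ds.target_id}: non-finite score")
    rates = {}
    for k in top_ks:
        n_ok = 0
        for ds in sets:
            top = _ranked_poses(ds.poses)[:k]
            if any(p[1] <= rmsd_cut for p in top):
                n_ok += 1
        rates[k] = 100.0 * n_ok / len(sets)
    return rates


# ---------------------------------------------------------------------------
# Screening power


def _top_n(n_candidates: int, alpha: float) -> int:
    return int(math.ceil(alpha * n_candidates))


def enrichment_factor(candidates, alpha: float) -> float:
    """EF_alpha = TB_alpha / (alpha * TB_tot) over one target's candidates."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    tb_tot = sum(c[2] for c in candidates)
    if tb_tot == 0:
        raise ValueError("no true binders")
    ranked = sorted(candidates, key=lambda c: (-c[1], c[0]))
    ntop = _top_n(len(candidates), alpha)
    tb_alpha = sum(c[2] for c in ranked[:ntop])
    return tb_alpha / (alpha * tb_tot)


def screening_power(sets: Sequence[ScreeningSet],
                    alphas: Sequence[float] = (0.01, 0.05, 0.10)) -> dict:
    """Forward success rates, mean EF_alpha, and reverse success rates.

    Forward: fraction of targets whose best binder ranks in the top
    alpha fraction. Reverse: for each ligand that truly binds >= 1 target,
    rank all targets by that ligand's score and check whether a true
    target appears in the top alpha fraction of targets.
    """
    if not sets:
        raise ValueError("no screening sets")
    out = {"forward_success": {}, "ef": {}, "reverse_success": {}}
    usable = []
    for ss in sets:
        if not any(c[2] for c in ss.candidates):
            warnings.warn(f"target {ss.target_id}: zero true binders; skipped")
            continue
        usable.append(ss)
    if not usable:
        raise ValueError("no screening set with true binders")

    for alpha in alphas:
        n_ok, efs = 0, []
        for ss in usable:
            ranked = sorted(ss.candidates, key=lambda c: (-c[1], c[0]))
            ntop = _top_n(len(ss.candidates), alpha)
            if any(c[3] for c in ranked[:ntop]):
                n_ok += 1
            efs.append(enrichment_factor(ss.candidates, alpha))
        out["forward_success"][alpha] = 100.0 * n_ok / len(usable)
        out["ef"][alpha] = float(np.mean(efs))

    # reverse screening: ligand-major ranking of targets
    per_ligand: dict[str, list[tuple[str, float, bool]]] = {}
    binds: dict[str, bool] = {}
    for ss in usable:
        for lid, score, is_tb, _ in ss.candidates:
            per_ligand.setdefault(lid, []).append((ss.target_id, score, is_tb))
            binds[lid] = binds.get(lid, False) or is_tb
    active = [lid for lid, b in binds.items() if b]
    for alpha in alphas:
        n_ok = 0
        for lid in active:
            ranked = sorted(per_ligand[lid], key=lambda t: (-t[1], t[0]))
            ntop = _top_n(len(ranked), alpha)
            if any(t[2] for t in ranked[:ntop]):
                n_ok += 1
        out["reverse_success"][alpha] = 100.0 * n_ok / len(active) if active else float("nan")
    return out


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_ci(metric: Callable[[ScoredSet], float], s: ScoredSet,
                 n_rep: int = 10000, level: float = 0.90,
                 seed: int = 0, max_redraws: int = 100) -> tuple[float, float]:
    """Seeded paired percentile bootstrap interval for a ScoredSet metric."""
    if n_rep < 1 or not 0 < level < 1:
        raise ValueError("need n_rep >= 1 and 0 < level < 1")
    rng = np.random.default_rng(seed)
    n = len(s.ids)
    vals = np.empty(n_rep)
    for b in range(n_rep):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            try:
                vals[b] = metric(s.subset(idx))
                break
            except ValueError:
                continue  # degenerate resample (e.g. constant): redraw
        else:
            raise ValueError("metric undefined on too many bootstrap resamples")
    lo, hi = np.percentile(vals, [50 * (1 - level), 50 * (1 + level)])
    return float(lo), float(hi)
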