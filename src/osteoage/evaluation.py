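"""Evaluation: MAE / Pearson / concordance metrics and stratified k-fold CV.

Agreement between predicted and true ages is summarized by

* **MAE** ``(1/n) sum |y_i - yhat_i|`` (years),
* **Pearson's rho** ``cov(y, yhat) / (sigma_y sigma_yhat)``,
* **Lin's CCC** ``2 rho sigma_y sigma_yhat /
  (sigma_y^2 + sigma_yhat^2 + (mu_y - mu_yhat)^2)``,

with population (1/n) moments throughout. CCC penalizes both decorrelation
and location/scale shift, so |CCC| <= |rho| always.

The cross-validation protocol partitions subjects into k folds stratified
by age decade x sex, trains one model per fold on the remaining subjects
(with an inner 90/10 stratified train/validation split for the LR
scheduler and checkpoint selection), evaluates on the held-out fold, and
reports per-fold metrics plus their mean +/- population std.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .networks import LateFusionEnsemble, NetworkConfig, build_model
from .training import Sample, TrainConfig, evaluate, train, train_late_ensemble

__all__ = [
    "EvalVector",
    "FoldPlan",
    "MetricReport",
    "UndefinedCorrelationError",
    "mae",
    "pearson",
    "ccc",
    "scatter_data",
    "kfold_split",
    "cross_validate",
    "mean_baseline_cv",
]


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined when either side has zero variance."""


@dataclass
class EvalVector:
    """Paired true and predicted ages with optional subject ids."""

    y: np.ndarray
    yhat: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        self.yhat = np.asarray(self.yhat, dtype=np.float64)
        if self.y.shape != self.yhat.shape or self.y.ndim != 1:
            raise ValueError("y and yhat must be equal-length 1-D vectors")
        if not (np.isfinite(self.y).all() and np.isfinite(self.yhat).all()):
            raise ValueError("ages must be finite")


def _as_pair(v, yhat=None):
    if yhat is not None:
        return np.asarray(v, dtype=np.float64), np.asarray(yhat, dtype=np.float64)
    return v.y, v.yhat


def mae(v, yhat=None) -> float:
    """Mean absolute error in years. Accepts an EvalVector or (y, yhat)."""
    y, p = _as_pair(v, yhat)
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(y - p)))


def pearson(v, yhat=None) -> float:
    """Pearson correlation with population (1/n) moments."""
    y, p = _as_pair(v, yhat)
    if y.size < 2:
        raise ValueError("need at least two pairs")
    sy = y.std()
    sp = p.std()
    if sy == 0 or sp == 0:
        raise UndefinedCorrelationError("undefined correlation: zero variance input")
    cov = np.mean((y - y.mean()) * (p - p.mean()))
    return float(cov / (sy * sp))


def ccc(v, yhat=None) -> float:
    """Lin's concordance correlation coefficient, population moments.

    Degenerate cases are defined explicitly: two identical constant vectors
    give 1; two constant vectors with different means give 0.
    """
    y, p = _as_pair(v, yhat)
    if y.size < 2:
        raise ValueError("need at least two pairs")
    vy = y.var()
    vp = p.var()
    dmu = y.mean() - p.mean()
    if vy == 0 and vp == 0:
        return 1.0 if dmu == 0 else 0.0
    cov = np.mean((y - y.mean()) * (p - p.mean()))
    return float(2 * cov / (vy + vp + dmu**2))


def scatter_data(v: EvalVector) -> pd.DataFrame:
    """Per-subject (true age, predicted age, residual) table for scatter plots."""
    if v.y.size == 0:
        raise ValueError("empty input")
    ids = v.ids if v.ids is not None else [str(i) for i in range(v.y.size)]
    return pd.DataFrame(
        {
            "subject_id": ids,
            "true_age": v.y,
            "predicted_age": v.yhat,
            "residual": v.yhat - v.y,
        }
    )


@dataclass
class FoldPlan:
    """k disjoint, stratification-balanced partitions of subject ids."""

    folds: list[list[str]]
    seed: int
    strata: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.folds)

    def validate(self) -> None:
        all_ids = [sid for fold in self.folds for sid in fold]
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("folds are not disjoint")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes differ by more than one")


def _stratum(age: float, sex: int, bin_width: float = 10.0) -> tuple[int, int]:
    return int(age // bin_width), int(sex)


def kfold_split(subjects, k: int = 10, seed: int = 0, bin_width: float = 10.0) -> FoldPlan:
    """Stratified k-fold partition of ``subjects`` (id, age, sex) records.

    ``subjects`` is an iterable of objects with ``sid``/``age``/``sex``
    attributes (e.g. :class:`~osteoage.training.Sample`) or mapping rows
    with those keys. Subjects are grouped into age-decade x sex strata;
    within each stratum the shuffled members are dealt cyclically across
    folds, with the deal position carried between strata so global fold
    sizes also differ by at most one. Depends only on the id set, not on
    input order.
    """

    def fields(s):
        if hasattr(s, "sid"):
            return s.sid, s.age, s.sex
        return s["subject_id"], s["age_years"], s["sex"]

    records = sorted((fields(s) for s in subjects), key=lambda r: r[0])
    if len(records) < k:
        raise ValueError(f"need at least k={k} subjects, got {len(records)}")
    if len({r[0] for r in records}) != len(records):
        raise ValueError("duplicate subject ids")

    rng = np.random.default_rng(seed)
    strata: dict[tuple[int, int], list[str]] = {}
    for sid, age, sex in records:
        strata.setdefault(_stratum(age, sex, bin_width), []).append(sid)

    folds: list[list[str]] = [[] for _ in range(k)]
    cursor = int(rng.integers(k))
    for key in sorted(strata):
        members = list(strata[key])
        rng.shuffle(members)
        for sid in members:
            folds[cursor % k].append(sid)
            cursor += 1
    plan = FoldPlan(folds=folds, seed=seed, strata={str(key): v for key, v in strata.items()})
    plan.validate()
    return plan


@dataclass
class MetricReport:
    """Per-fold MAE / Pearson / CCC plus aggregate mean +/- population std."""

    per_fold: pd.DataFrame
    config_tag: str = ""

    @property
    def aggregate(self) -> dict[str, tuple[float, float]]:
        out = {}
        for col in ("mae", "pearson", "ccc"):
            vals = self.per_fold[col].to_numpy(dtype=float)
            out[col] = (float(vals.mean()), float(vals.std()))
        return out

    def summary(self) -> str:
        agg = self.aggregate
        lines = [f"configuration: {self.config_tag}"]
        lines.append(self.per_fold.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        lines.append(
            "means +/- std: "
            + "  ".join(f"{k}={m:.3f} +/- {s:.3f}" for k, (m, s) in agg.items())
        )
        return "\n".join(lines)


def _inner_split(samples: list[Sample], val_fraction: float, rng: np.random.Generator):
    """Stratified (age decade x sex) train/validation split inside a CV fold."""
    strata: dict[tuple[int, int], list[int]] = {}
    for i, s in enumerate(samples):
        strata.setdefault(_stratum(s.age, s.sex), []).append(i)
    val_idx: list[int] = []
    for key in sorted(strata):
        idx = list(strata[key])
        rng.shuffle(idx)
        n_val = max(1, int(round(len(idx) * val_fraction))) if len(idx) > 1 else 0
        val_idx.extend(idx[:n_val])
    val_set = set(val_idx)
    if not val_set or len(val_set) == len(samples):
        # degenerate strata; fall back to one held-out subject
        val_set = {int(rng.integers(len(samples)))}
    train_set = [samples[i] for i in range(len(samples)) if i not in val_set]
    val = [samples[i] for i in sorted(val_set)]
    return train_set, val


def cross_validate(
    dataset: list[Sample],
    net_config: NetworkConfig,
    train_config: TrainConfig,
    fold_plan: FoldPlan,
    inner_val_fraction: float = 0.1,
) -> tuple[MetricReport, pd.DataFrame]:
    """Run the full k-fold protocol; returns (report, scatter table).

    One model is trained per fold on the subjects outside it and evaluated
    on the held-out fold. A leakage guard asserts that no test subject
    enters its model's training or inner-validation data. The scatter table
    pools the held-out predictions of all folds (every subject appears
    exactly once).
    """
    fold_plan.validate()
    by_id = {s.sid: s for s in dataset}
    missing = [sid for fold in fold_plan.folds for sid in fold if sid not in by_id]
    if missing:
        raise ValueError(f"fold plan references unknown subjects: {missing[:5]}")

    rows = []
    scatter_frames = []
    for f, fold_ids in enumerate(fold_plan.folds):
        test = [by_id[sid] for sid in fold_ids]
        pool = [s for s in dataset if s.sid not in set(fold_ids)]
        rng = np.random.default_rng(np.random.SeedSequence((fold_plan.seed, f)))
        tr, va = _inner_split(pool, inner_val_fraction, rng)

        test_ids = {s.sid for s in test}
        assert not (test_ids & {s.sid for s in tr}), f"leakage into training set, fold {f}"
        assert not (test_ids & {s.sid for s in va}), f"leakage into validation set, fold {f}"

        cfg = replace(net_config, seed=net_config.seed + 1000 * f)
        tcfg = replace(train_config, seed=train_config.seed + 1000 * f)
        model = build_model(cfg)
        try:
            if isinstance(model, LateFusionEnsemble):
                train_late_ensemble(model, tr, va, tcfg)
            else:
                train(model, tr, va, tcfg)
        except Exception as err:
            raise RuntimeError(f"training failed in fold {f}: {err}") from err

        pred = evaluate(model, test, tcfg)
        v = EvalVector(
            y=np.array([s.age for s in test]), yhat=pred, ids=[s.sid for s in test]
        )
        rows.append(
            {"fold": f, "n": len(test), "mae": mae(v), "pearson": pearson(v), "ccc": ccc(v)}
        )
        frame = scatter_data(v)
        frame.insert(0, "fold", f)
        scatter_frames.append(frame)

    tag = net_config.fusion if net_config.fusion != "none" else net_config.modality
    report = MetricReport(per_fold=pd.DataFrame(rows), config_tag=tag)
    return report, pd.concat(scatter_frames, ignore_index=True)


def mean_baseline_cv(dataset: list[Sample], fold_plan: FoldPlan) -> MetricReport:
    """Predict-the-training-mean baseline under the same fold plan.

    Pearson/CCC are undefined for a constant predictor, so those columns
    are reported as NaN; the baseline exists for its MAE.
    """
    fold_plan.validate()
    by_id = {s.sid: s for s in dataset}
    rows = []
    for f, fold_ids in enumerate(fold_plan.folds):
        test_ages = np.array([by_id[sid].age for sid in fold_ids])
        train_ages = np.array(
            [s.age for s in dataset if s.sid not in set(fold_ids)]
        )
        pred = np.full_like(test_ages, train_ages.mean())
        rows.append(
            {
                "fold": f,
                "n": len(test_ages),
                "mae": mae(test_ages, pred),
                "pearson": np.nan,
                "ccc": 0.0,
            }
        )
    return MetricReport(per_fold=pd.DataFrame(rows), config_tag="mean-baseline")
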