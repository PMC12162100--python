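"""Evaluation workflow: interval metrics, leave-one-subject-out
cross-validation, unified-model training and the perturbation-robustness
experiment.

Two metrics summarise an interval predictor on labeled data: *coverage*, the
fraction of samples whose true malignant fraction lies inside its interval
(boundary values count as covered),

    Coverage = (1/n) sum_i 1( lower_i <= y_i <= upper_i ),

and *average length*, the mean interval width

    L_avg = (1/n) sum_i |upper_i - lower_i|.

A valid predictor at significance level alpha has coverage >= 1 - alpha; at
fixed coverage, shorter intervals are more informative.

Leave-one-out cross-validation holds out one subject's simulated dataset at
a time, pools the remaining subjects, splits the pool 7:3 into proper
training and calibration sets, fits the preprocessing and the quantile
network on the pool, conformalizes, and evaluates on the held-out subject --
so each fold tests generalisation to an unseen individual with no leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bulk import BulkDataset, concat_bulk
from .conformal import ConformalCalibration, calibrate, conformalize, split_train_calib
from .preprocess import (TransformSpec, align_and_filter_genes, apply_transform,
                         perturb_dataset)
from .quantile_net import QuantileModel, QuantileModelConfig, build_network, \
    predict_quantiles, train


@dataclass
class IntervalReport:
    """Per-sample intervals plus the coverage / average-length summary."""

    per_sample: pd.DataFrame
    coverage: float | None
    avg_length: float
    alpha: float
    dataset_id: str


@dataclass
class FittedPipeline:
    """A trained fold: transform spec, quantile network and (optionally) the
    conformal calibration. ``calibration=None`` is the no-calibration
    ablation: raw network quantiles are reported."""

    model: QuantileModel
    calibration: ConformalCalibration | None
    spec: TransformSpec

    @property
    def adjustment(self) -> float:
        return 0.0 if self.calibration is None else self.calibration.adjustment


def coverage(lower, upper, y) -> float:
    """Fraction of samples with lower_i <= y_i <= upper_i (non-strict)."""
    lower, upper, y = (np.asarray(a, dtype=float) for a in (lower, upper, y))
    if y.size == 0:
        raise ValueError("coverage of an empty sample set is undefined")
    if not (lower.shape == upper.shape == y.shape):
        raise ValueError("lower, upper and y must have equal lengths")
    return float(np.mean((lower <= y) & (y <= upper)))


def avg_length(lower, upper) -> float:
    """Mean absolute interval width."""
    lower, upper = np.asarray(lower, dtype=float), np.asarray(upper, dtype=float)
    if lower.size == 0:
        raise ValueError("avg_length of an empty sample set is undefined")
    if lower.shape != upper.shape:
        raise ValueError("lower and upper must have equal lengths")
    return float(np.mean(np.abs(upper - lower)))


def _derive_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def fit_pipeline(train_pool: BulkDataset, alpha: float,
                 config: QuantileModelConfig, seed: int,
                 test: BulkDataset | None = None,
                 use_calibration: bool = True,
                 apply_tfidf: bool = True,
                 variance_threshold: float = 0.1,
                 train_frac: float = 0.7) -> FittedPipeline:
    """Fit preprocessing, quantile network and conformal calibration on a
    pooled training dataset.

    The transform spec intersects gene identities with ``test`` (if given)
    and filters on raw training variance; the pooled matrix is transformed
    once, then split ``train_frac`` : 1 - ``train_frac`` into the proper
    training and calibration parts. With ``use_calibration=False`` the whole
    pool trains the network and no adjustment is computed.
    """
    if train_pool.fractions is None:
        raise ValueError("training pool must carry known fractions")
    spec = align_and_filter_genes(train_pool, test,
                                  variance_threshold=variance_threshold,
                                  apply_tfidf=apply_tfidf)
    ss = np.random.SeedSequence([int(seed), 0])
    split_seed, net_seed = (_derive_seed(s) for s in ss.spawn(2))
    if use_calibration:
        train_part, calib_part = split_train_calib(train_pool, train_frac=train_frac,
                                                   seed=split_seed)
    else:
        train_part, calib_part = train_pool, None
    X_train = apply_transform(train_part, spec)
    cfg = replace(config, alpha=alpha, seed=net_seed)
    model = build_network(cfg, X_train.shape[1])
    model.transform_spec = spec
    train(model, X_train, train_part.fractions, cfg)
    calibration = None
    if use_calibration:
        X_cal = apply_transform(calib_part, spec)
        q_lo, q_hi = predict_quantiles(model, X_cal)
        calibration = calibrate(q_lo, q_hi, calib_part.fractions, alpha)
    return FittedPipeline(model=model, calibration=calibration, spec=spec)


def predict_intervals(pipeline: FittedPipeline, data: BulkDataset,
                      clip: bool = True) -> IntervalReport:
    """Apply a fitted fold to a dataset and summarise the intervals."""
    X = apply_transform(data, pipeline.spec)
    q_lo, q_hi = predict_quantiles(pipeline.model, X)
    lower, upper = conformalize(q_lo, q_hi, pipeline.adjustment, clip=clip)
    alpha = pipeline.model.alpha
    table = pd.DataFrame({
        "sample_id": [f"{data.subject_id}_{i}" for i in range(data.n_samples)],
        "lower": lower,
        "upper": upper,
    })
    cov = None
    if data.fractions is not None:
        table["y_true"] = data.fractions
        table["covered"] = (lower <= data.fractions) & (data.fractions <= upper)
        cov = coverage(lower, upper, data.fractions)
    return IntervalReport(per_sample=table, coverage=cov,
                          avg_length=avg_length(lower, upper),
                          alpha=alpha, dataset_id=data.subject_id)


def loo_cv(datasets: list[BulkDataset], alpha: float,
           config: QuantileModelConfig, seed: int = 0,
           use_calibration: bool = True, apply_tfidf: bool = True,
           variance_threshold: float = 0.1,
           return_pipelines: bool = False):
    """Leave-one-subject-out cross-validation.

    For each held-out dataset the other k - 1 are pooled, a pipeline is
    fitted (7:3 train/calibration split) and evaluated on the held-out
    subject. Fully deterministic for a fixed seed.
    """
    k = len(datasets)
    if k < 2:
        raise ValueError("leave-one-out needs at least 2 datasets")
    reports, pipelines = [], []
    for i, held_out in enumerate(datasets):
        pool = concat_bulk([d for j, d in enumerate(datasets) if j != i])
        assert held_out.subject_id not in {d.subject_id for j, d in enumerate(datasets) if j != i}
        fold_seed = _derive_seed(np.random.SeedSequence([int(seed), i + 1]))
        pipe = fit_pipeline(pool, alpha, config, fold_seed, test=held_out,
                            use_calibration=use_calibration,
                            apply_tfidf=apply_tfidf,
                            variance_threshold=variance_threshold)
        report = predict_intervals(pipe, held_out)
        reports.append(report)
        pipelines.append(pipe)
    if return_pipelines:
        return reports, pipelines
    return reports


def train_unified(datasets: list[BulkDataset], alpha: float,
                  config: QuantileModelConfig, seed: int = 0,
                  use_calibration: bool = True,
                  apply_tfidf: bool = True,
                  variance_threshold: float = 0.1) -> FittedPipeline:
    """Pool every subject's dataset and fit one pipeline (7:3 split) for
    prediction on external bulk samples."""
    if not datasets:
        raise ValueError("need at least 1 dataset")
    pool = concat_bulk(datasets) if len(datasets) > 1 else datasets[0]
    return fit_pipeline(pool, alpha, config, seed,
                        use_calibration=use_calibration,
                        apply_tfidf=apply_tfidf,
                        variance_threshold=variance_threshold)


def robustness_experiment(datasets: list[BulkDataset], alpha: float = 0.1,
                          lambdas=(0.01, 0.05, 0.1),
                          config: QuantileModelConfig | None = None,
                          seed: int = 0, include_control: bool = True) -> pd.DataFrame:
    """Apply leave-one-out-trained pipelines to noise-perturbed test data.

    Training and calibration use unperturbed data; only the held-out
    expression is perturbed, at each noise level lambda (variance of the
    added Gaussian noise = lambda x expression). A lambda = 0 control row is
    included by default. Returns a tidy table (lam, dataset, coverage,
    avg_length).
    """
    if config is None:
        config = QuantileModelConfig()
    lams = ([0.0] if include_control else []) + [float(l) for l in lambdas]
    reports, pipelines = loo_cv(datasets, alpha, config, seed=seed,
                                return_pipelines=True)
    rows = []
    ss = np.random.SeedSequence([int(seed), 7])
    perturb_seeds = ss.spawn(len(lams) * len(datasets))
    s = 0
    for lam in lams:
        for i, held_out in enumerate(datasets):
            if lam == 0.0:
                report = reports[i]
            else:
                noisy = perturb_dataset(held_out, lam,
                                        np.random.default_rng(perturb_seeds[s]))
                report = predict_intervals(pipelines[i], noisy)
            s += 1
            rows.append({"lam": lam, "dataset": held_out.subject_id,
                         "coverage": report.coverage,
                         "avg_length": report.avg_length})
    return pd.DataFrame(rows)
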