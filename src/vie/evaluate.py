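"""Threshold-free evaluation: AUC, AUPRC, bootstrap CIs, and the ablation harness.

AUC is the rank-based Mann-Whitney estimate (ties count 1/2); AUPRC is the
step-wise average precision with tied scores treated as one threshold block
(no linear interpolation between PR points). Confidence intervals are
stratified percentile bootstrap: positives and negatives are resampled
separately so both classes are present in every resample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class EvalReport:
    auc: float
    auprc: float
    ci_auc: tuple = (float("nan"), float("nan"))
    ci_auprc: tuple = (float("nan"), float("nan"))
    n_boot: int = 0
    per_replicate: pd.DataFrame | None = None

    def to_dict(self):
        return {"auc": self.auc, "auprc": self.auprc,
                "ci_auc": list(self.ci_auc), "ci_auprc": list(self.ci_auprc),
                "n_boot": self.n_boot}


def _check_labels(labels, need_both=True):
    labels = np.asarray(labels)
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be binary 0/1")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("labels contain no positives")
    if need_both and n_pos == labels.size:
        raise ValueError("labels contain no negatives")
    return labels.astype(int)


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + P(equal)/2."""
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    ranks = rankdata(scores)  # midranks handle ties as 1/2
    n1 = labels.sum()
    n0 = labels.size - n1
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auprc(scores, labels) -> float:
    """Step-wise average precision over distinct-score threshold blocks.

    AP = sum_k (R_k - R_{k-1}) * P_k where (P_k, R_k) are precision/recall
    after including the k-th distinct score value (descending). Equals the
    usual average precision on tie-free inputs; a constant ranker scores the
    prevalence.
    """
    labels = _check_labels(labels, need_both=False)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="mergesort")
    s_sorted, y_sorted = scores[order], labels[order]
    # ends of tie blocks
    block_end = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    tp = np.cumsum(y_sorted)[block_end]
    fp = (block_end + 1) - tp
    precision = tp / (tp + fp)
    recall = tp / labels.sum()
    d_recall = np.diff(np.r_[0.0, recall])
    return float(np.sum(d_recall * precision))


METRICS = {"auc": auc, "auprc": auprc}


def bootstrap_ci(scores, labels, metric="auprc", n_boot: int = 1000,
                 seed: int = 0, level: float = 0.95):
    """Stratified percentile bootstrap interval for a ranking metric."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    fn = METRICS[metric] if isinstance(metric, str) else metric
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    pos, neg = np.flatnonzero(labels == 1), np.flatnonzero(labels == 0)
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(pos, size=pos.size, replace=True),
                              rng.choice(neg, size=neg.size, replace=True)])
        stats[b] = fn(scores[idx], labels[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def evaluate_scores(scores, labels, n_boot: int = 1000, seed: int = 0,
                    level: float = 0.95) -> EvalReport:
    """Point estimates plus bootstrap CIs in one report."""
    a = auc(scores, labels)
    ap = auprc(scores, labels)
    ci_a = bootstrap_ci(scores, labels, "auc", n_boot, seed, level)
    ci_p = bootstrap_ci(scores, labels, "auprc", n_boot, seed + 1, level)
    return EvalReport(auc=a, auprc=ap, ci_auc=ci_a, ci_auprc=ci_p, n_boot=n_boot)


def ablation_harness(sim_config, variant_list, n_repeats: int = 10, seed: int = 0,
                     training_config=None, include_oracle: bool = True):
    """Repeat simulate -> split -> train -> test for each model variant.

    Each repeat draws a fresh cohort (seed + index), splits 6:2:2, trains
    every requested variant with the same budget, and records test AUC/AUPRC;
    the oracle row ranks by the true event probability without any training.
    Returns (summary, per_replicate) where the summary holds mean and sd per
    variant.
    """
    from .simulate import SimulationConfig, simulate_dataset, train_val_test_split
    from .training import TrainingConfig, train, predict_risk

    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    records = []
    for rep in range(n_repeats):
        cfg = SimulationConfig(**{**sim_config.__dict__, "seed": sim_config.seed + rep})
        data = simulate_dataset(cfg)
        tr, va, te = train_val_test_split(cfg.n, seed=cfg.seed)
        if include_oracle:
            records.append({"variant": "oracle", "repeat": rep,
                            "auc": auc(data.oracle_risk[te], data.y[te]),
                            "auprc": auprc(data.oracle_risk[te], data.y[te])})
        for variant in variant_list:
            if variant == "oracle":
                continue
            base = training_config.__dict__ if training_config is not None else {}
            tcfg = TrainingConfig(**{**base, "variant": variant,
                                     "seed": seed + 1000 * rep})
            model = train(data.X[tr], data.y[tr], data.X[va], data.y[va], tcfg)
            risk = predict_risk(model, data.X[te], seed=seed + rep)
            records.append({"variant": variant, "repeat": rep,
                            "auc": auc(risk, data.y[te]),
                            "auprc": auprc(risk, data.y[te])})
    per_replicate = pd.DataFrame.from_records(records)
    summary = (per_replicate.groupby("variant")[["auc", "auprc"]]
               .agg(["mean", "std"]))
    summary.columns = ["_".join(c) for c in summary.columns]
    return summary, per_replicate
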