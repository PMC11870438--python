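"""Test-set metrics and the eQTL-style SNP classification pipeline.

Metrics: per-track Pearson r and coefficient of determination r² over
concatenated bins of the withheld windows, with per-assay-group averages.

Variant scoring: predict all tracks for a window centred on the variant
under the reference and the alternate allele, form per-bin differences
and log-ratios, summarise each per track (signed log of the bin-sum of
differences; L2 norm of the log-ratios), and concatenate the summaries
across an ensemble of models (one per data split in the full protocol).
A random forest on those features separates causal from null variants;
reported metrics are cross-validated AUROC and the Spearman rank
correlation of classifier scores.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sstats

from .seqdata import Assay, SequenceWindow, TrackMeta, one_hot_encode

__all__ = ["TrackMetrics", "VariantScore", "track_metrics", "predict_variant",
           "snp_classifier", "auroc_rank", "ClassifierReport"]

EPS_LOG = 1e-6   # pseudocount inside log-ratios


@dataclasses.dataclass
class TrackMetrics:
    pearson: np.ndarray          # (T,) with NaN where undefined
    r2: np.ndarray               # (T,)
    mean_pearson: float
    mean_r2: float
    by_assay: dict[str, tuple[float, float]]
    n_undefined: int


@dataclasses.dataclass
class VariantScore:
    variant_id: str
    log_sum_diff: np.ndarray     # (n_models, T) signed-log bin-sum of differences
    l2_log_ratio: np.ndarray     # (n_models, T)

    @property
    def features(self) -> np.ndarray:
        """Concatenation across ensemble members and summary types."""
        return np.concatenate([self.log_sum_diff.ravel(),
                               self.l2_log_ratio.ravel()])


def track_metrics(pred: np.ndarray, obs: np.ndarray,
                  meta: Sequence[TrackMeta] | None = None) -> TrackMetrics:
    """Pearson r and r² per track over concatenated bins.

    r² is 1 − SSE/SST against the observed mean (it can be negative for a
    bad fit).  Tracks whose observed values have zero variance are
    flagged undefined (NaN) and excluded from the means, with a count.
    """
    pred = np.asarray(pred, dtype=np.float64)
    obs = np.asarray(obs, dtype=np.float64)
    if pred.shape != obs.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {obs.shape}")
    if pred.shape[0] < 2:
        raise ValueError("need at least 2 bins")
    T = pred.shape[1]
    r = np.full(T, np.nan)
    r2 = np.full(T, np.nan)
    for t in range(T):
        o, p = obs[:, t], pred[:, t]
        if np.ptp(o) == 0.0:        # constant track: r and r² undefined
            continue
        sst = float(np.sum((o - o.mean()) ** 2))
        if p.std() > 0:
            r[t] = float(np.corrcoef(p, o)[0, 1])
        sse = float(np.sum((o - p) ** 2))
        r2[t] = 1.0 - sse / sst
    ok = ~np.isnan(r2)
    by_assay: dict[str, tuple[float, float]] = {}
    if meta is not None:
        for assay in {m.assay for m in meta}:
            idx = [i for i, m in enumerate(meta) if m.assay is Assay(assay)]
            sel = [i for i in idx if ok[i]]
            if sel:
                by_assay[Assay(assay).value] = (
                    float(np.nanmean(r[sel])), float(np.mean(r2[sel])))
    return TrackMetrics(
        pearson=r, r2=r2,
        mean_pearson=float(np.nanmean(r[ok])) if ok.any() else float("nan"),
        mean_r2=float(np.mean(r2[ok])) if ok.any() else float("nan"),
        by_assay=by_assay, n_undefined=int((~ok).sum()))


def _signed_log(s: np.ndarray) -> np.ndarray:
    """sign(S)·log(1+|S|): keeps the sign, compresses the scale."""
    return np.sign(s) * np.log1p(np.abs(s))


def predict_variant(models: Sequence[Callable[[np.ndarray], np.ndarray]],
                    window: SequenceWindow,
                    variant_pos: int,
                    ref: str,
                    alt: str,
                    variant_id: str = "",
                    crop: int = 0) -> VariantScore:
    """Score one single-base substitution with an ensemble of models.

    ``variant_pos`` is 0-based within the window; the reference base must
    match the window sequence.  Per model and track the per-bin
    difference d = pred_alt − pred_ref and log-ratio
    ℓ = log(pred_alt+ε) − log(pred_ref+ε) are summarised as
    sign(Σd)·log(1+|Σd|) and √(Σℓ²); ``crop`` bins at each end are
    excluded first.
    """
    L = window.length
    if not (0 <= variant_pos < L):
        raise ValueError(f"variant position {variant_pos} outside window")
    seq = window.sequence()
    if seq[variant_pos] != ref.upper():
        raise ValueError(
            f"allele mismatch at {window.chrom}:{window.start + variant_pos}: "
            f"reference sequence has {seq[variant_pos]!r}, variant claims {ref!r}")
    oh_ref = window.onehot
    oh_alt = oh_ref.copy()
    oh_alt[variant_pos] = one_hot_encode(alt)[0]
    log_sums, l2s = [], []
    for f in models:
        pr = np.asarray(f(oh_ref), dtype=np.float64)
        pa = np.asarray(f(oh_alt), dtype=np.float64)
        B = pr.shape[0]
        if crop:
            pr, pa = pr[crop:B - crop], pa[crop:B - crop]
        d = pa - pr
        lr = np.log(pa + EPS_LOG) - np.log(pr + EPS_LOG)
        log_sums.append(_signed_log(d.sum(axis=0)))
        l2s.append(np.sqrt((lr ** 2).sum(axis=0)))
    return VariantScore(variant_id, np.stack(log_sums), np.stack(l2s))


def auroc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC by the Mann-Whitney rank formula (ties handled by midranks)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sstats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclasses.dataclass
class ClassifierReport:
    auroc: float
    spearman: float
    cv_scores: np.ndarray        # out-of-fold classifier probabilities
    classifier: object


def snp_classifier(scores: Sequence[VariantScore],
                   labels: Sequence[int],
                   seed: int,
                   target: Sequence[float] | None = None,
                   n_estimators: int = 1000,
                   n_folds: int = 5) -> ClassifierReport:
    """Random forest on variant-score summaries, evaluated out-of-fold.

    AUROC is computed from stratified cross-validated probabilities (so
    the number reflects held-out variants); Spearman correlates the
    classifier score with ``target`` (e.g. a fine-mapping probability or
    a true effect magnitude), defaulting to the labels.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import StratifiedKFold, cross_val_predict

    X = np.stack([s.features for s in scores])
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    cv = StratifiedKFold(n_splits=min(n_folds, np.bincount(y).min()),
                         shuffle=True, random_state=seed)
    prob = cross_val_predict(clf, X, y, cv=cv, method="predict_proba")[:, 1]
    clf.fit(X, y)
    tgt = np.asarray(target if target is not None else y, dtype=np.float64)
    rho = float(sstats.spearmanr(prob, tgt).statistic)
    return ClassifierReport(auroc=auroc_rank(prob, y), spearman=rho,
                            cv_scores=prob, classifier=clf)
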