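"""Discriminability statistics for painless vs pain segments.

Four tools, matching how repeated pain-stimulation designs are usually
analyzed:

* :func:`fishers_ratio` — linear discriminating power
  ``|mean0 - mean1| / (var0 + var1)`` (sample variances).
* :func:`auroc` — the Mann-Whitney probability that a random pain segment
  outscores a random painless one, with a subject-stratified bootstrap CI
  (segments within a subject are correlated, so subjects — not segments —
  are resampled).
* :func:`ks_normality` — one-sample Kolmogorov-Smirnov test against a normal
  with the sample mean and SD, reported for information.
* :func:`nested_rank_test` — a subject-nested permutation test: the
  statistic is the mean across subjects of the within-subject Wilcoxon
  rank-sum Z, and the null distribution is built by permuting labels within
  each subject, which respects between-subject level differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .records import ValidationError


def fishers_ratio(x0: np.ndarray, x1: np.ndarray) -> float:
    """``|mean(x0) - mean(x1)| / (var(x0) + var(x1))`` with (n-1) variances."""
    x0 = np.asarray(x0, float)
    x1 = np.asarray(x1, float)
    if x0.size < 2 or x1.size < 2:
        raise ValidationError("each class needs at least 2 values")
    denom = x0.var(ddof=1) + x1.var(ddof=1)
    if denom == 0:
        raise ValidationError("both classes have zero variance")
    return float(abs(x0.mean() - x1.mean()) / denom)


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank-sum identity (ties count one half)."""
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = sps.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def auroc(
    scores: np.ndarray,
    labels: np.ndarray,
    subjects: np.ndarray | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """AUROC with a 95% bootstrap confidence interval.

    The point estimate is the Mann-Whitney pair-counting probability.  The CI
    resamples *subjects* with replacement when subject ids are given
    (stratified bootstrap; falls back to resampling segments otherwise) and
    takes the 2.5/97.5 percentiles over ``n_boot`` replicates.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValidationError("both classes must be present")
    auc = _auc_rank(scores, labels)

    rng = np.random.default_rng(seed)
    boots = []
    if subjects is not None:
        subjects = np.asarray(subjects)
        uniq = np.unique(subjects)
        groups = {s: np.flatnonzero(subjects == s) for s in uniq}
        for _ in range(n_boot):
            pick = rng.choice(uniq, size=uniq.size, replace=True)
            idx = np.concatenate([groups[s] for s in pick])
            if len(np.unique(labels[idx])) < 2:
                continue
            boots.append(_auc_rank(scores[idx], labels[idx]))
    else:
        n = scores.size
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            if len(np.unique(labels[idx])) < 2:
                continue
            boots.append(_auc_rank(scores[idx], labels[idx]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auc, float(lo), float(hi)


def ks_normality(x: np.ndarray) -> float:
    """One-sample KS p-value against ``Normal(mean(x), sd(x))``."""
    x = np.asarray(x, float)
    if x.size < 5:
        raise ValidationError("need at least 5 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("degenerate sample (zero standard deviation)")
    return float(sps.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def _rank_sum_z(values: np.ndarray, labels01: np.ndarray) -> float:
    """Standardized Wilcoxon rank-sum Z for one subject (tie-corrected)."""
    n = values.size
    n1 = int(labels01.sum())
    n0 = n - n1
    ranks = sps.rankdata(values)
    w = ranks[labels01 == 1].sum()
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(values, return_counts=True)
    tie = (counts**3 - counts).sum()
    var = n0 * n1 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return 0.0
    return float((w - mu) / np.sqrt(var))


def nested_rank_test(
    values: np.ndarray,
    labels: np.ndarray,
    subjects: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Subject-nested permutation rank test; returns a two-sided p-value.

    Statistic: mean over subjects of the within-subject rank-sum Z of class 1
    vs class 0.  The null permutes labels independently *within* each subject
    (between-subject differences never enter).  Subjects missing one of the
    two classes are excluded with a warning.  The p-value uses the
    add-one estimator ``(1 + #{|T*| >= |T|}) / (1 + n_perm)``.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    rng = np.random.default_rng(seed)

    per_subject: list[tuple[np.ndarray, np.ndarray]] = []
    for s in np.unique(subjects):
        m = subjects == s
        labs = labels[m]
        if len(np.unique(labs)) < 2:
            import logging

            logging.getLogger(__name__).warning("subject %s lacks a label class; excluded", s)
            continue
        per_subject.append((values[m], labs.astype(int)))
    if len(per_subject) < 1:
        raise ValidationError("no subject has both label classes")

    t_obs = np.mean([_rank_sum_z(v, l) for v, l in per_subject])
    t_null = np.zeros(n_perm)
    for v, l in per_subject:
        # ranks and the Z standardization are label-free, so a label
        # permutation is just a random size-n1 subset of the fixed ranks
        n = v.size
        n1 = int(l.sum())
        ranks = sps.rankdata(v)
        mu = n1 * (n + 1) / 2.0
        _, counts = np.unique(v, return_counts=True)
        tie = (counts**3 - counts).sum()
        var = (n - n1) * n1 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        if var <= 0:
            continue
        order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n1]
        w = ranks[order].sum(axis=1)
        t_null += (w - mu) / np.sqrt(var)
    t_null /= len(per_subject)
    extreme = int(np.sum(np.abs(t_null) >= abs(t_obs) - 1e-12))
    return float((1 + extreme) / (1 + n_perm))


@dataclass(frozen=True)
class FeatureComparison:
    """Summary statistics for one feature's painless-vs-pain contrast."""

    feature: str
    fishers_ratio: float
    auroc: float
    auroc_ci: tuple[float, float]
    p_value: float
    ks_p_class0: float
    ks_p_class1: float
    test_used: str = "nested_rank_permutation"


def compare_features(
    table, feature_columns: list[str], n_perm: int = 2000, n_boot: int = 2000, seed: int = 0
) -> list[FeatureComparison]:
    """Run the full statistics battery on a segment feature table.

    ``table`` is the DataFrame produced by the segments module (columns
    ``subject_id``, ``label`` and the features).  Returns one
    :class:`FeatureComparison` per feature.
    """
    out = []
    labels = table["label"].to_numpy()
    subjects = table["subject_id"].to_numpy()
    for i, feat in enumerate(feature_columns):
        v = table[feat].to_numpy(dtype=float)
        fr = fishers_ratio(v[labels == 0], v[labels == 1])
        auc, lo, hi = auroc(v, labels, subjects, n_boot=n_boot, seed=seed + i)
        p = nested_rank_test(v, labels, subjects, n_perm=n_perm, seed=seed + i)
        try:
            ks0 = ks_normality(v[labels == 0])
            ks1 = ks_normality(v[labels == 1])
        except ValidationError:
            ks0 = ks1 = float("nan")
        out.append(
            FeatureComparison(
                feature=feat,
                fishers_ratio=fr,
                auroc=auc,
                auroc_ci=(lo, hi),
                p_value=p,
                ks_p_class0=ks0,
                ks_p_class1=ks1,
            )
        )
    return out
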