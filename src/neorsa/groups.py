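"""Post-hoc respiratory-pattern grouping and interrater reliability.

Subjects are assigned post hoc to group 1 (regular deep respirations) or
group 2 (irregular shallow respirations) from the raters' consensus pattern;
with two raters a disagreement is a tie and the subject is excluded with a
logged reason. Group RSA metrics are compared with a two-sided Wilcoxon
rank-sum (Mann-Whitney) test — chosen over a t test because the groups are
small and PSD-derived metrics are right-skewed. Interrater reliability is
summarized by percent agreement and Cohen's weighted kappa

    kappa_w = 1 - sum(w_ij * o_ij) / sum(w_ij * e_ij)

with o the observed proportion table, e the outer product of its marginals,
and disagreement weights w_ij equal to 0/1 (unweighted), |i-j|/(k-1)
(linear) or ((i-j)/(k-1))^2 (quadratic) for k ordered categories.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .records import (
    ObservationRecord,
    PATTERN_IRREGULAR_SHALLOW,
    PATTERN_REGULAR_DEEP,
    RSASummary,
)

logger = logging.getLogger(__name__)

GROUP_REGULAR_DEEP = 1
GROUP_IRREGULAR_SHALLOW = 2


def assign_groups(observations: Sequence[ObservationRecord]):
    """Map subjects to respiratory-pattern groups by rater consensus.

    Returns ``(groups, excluded)`` where ``groups`` maps subject_id to 1
    (regular deep) or 2 (irregular shallow) and ``excluded`` lists subjects
    dropped for a rater tie.
    """
    if not observations:
        raise ValueError("no observations supplied")
    by_subject: dict = defaultdict(list)
    for obs in observations:
        by_subject[obs.subject_id].append(obs.pattern)

    groups: dict = {}
    excluded: list = []
    for subject_id, patterns in by_subject.items():
        counts = Counter(patterns)
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            logger.info("subject %s excluded: raters tied %s", subject_id, dict(counts))
            excluded.append(subject_id)
            continue
        pattern = top[0][0]
        groups[subject_id] = (
            GROUP_IRREGULAR_SHALLOW
            if pattern == PATTERN_IRREGULAR_SHALLOW
            else GROUP_REGULAR_DEEP
        )
    return groups, excluded


@dataclass
class GroupComparison:
    """Two-group comparison of RSA metrics."""

    metric: str
    n: dict
    means: dict  # {group: {"rsa_mean": .., "auc": ..}}
    ses: dict
    statistic: float
    p_value: float
    ratio_of_means: float  # group 2 / group 1, on `metric`

    def summary(self) -> str:
        lines = [
            "Two-group RSA comparison (Wilcoxon rank-sum, two-sided)",
            f"  metric tested: {self.metric}",
        ]
        for g, label in ((1, "regular deep"), (2, "irregular shallow")):
            lines.append(
                f"  group {g} ({label}): n={self.n[g]}, "
                f"rsa_mean={self.means[g]['rsa_mean']:.4g} "
                f"(SE {self.ses[g]['rsa_mean']:.3g}), "
                f"auc={self.means[g]['auc']:.4g} (SE {self.ses[g]['auc']:.3g})"
            )
        lines.append(
            f"  ratio of means (g2/g1, {self.metric}): {self.ratio_of_means:.4g}"
        )
        lines.append(f"  U={self.statistic:.4g}, p={self.p_value:.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "n": {str(k): int(v) for k, v in self.n.items()},
            "means": {str(k): v for k, v in self.means.items()},
            "ses": {str(k): v for k, v in self.ses.items()},
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "ratio_of_means": float(self.ratio_of_means),
        }


def _se(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0


def compare_rsa(
    summaries: Sequence[RSASummary],
    groups: dict,
    metric: str = "rsa_mean",
) -> GroupComparison:
    """Compare RSA metrics between the two respiratory-pattern groups."""
    if metric not in ("rsa_mean", "auc"):
        raise ValueError("metric must be 'rsa_mean' or 'auc'")
    vals: dict = {GROUP_REGULAR_DEEP: [], GROUP_IRREGULAR_SHALLOW: []}
    both: dict = {GROUP_REGULAR_DEEP: {"rsa_mean": [], "auc": []},
                  GROUP_IRREGULAR_SHALLOW: {"rsa_mean": [], "auc": []}}
    for s in summaries:
        g = groups.get(s.subject_id)
        if g is None:
            continue
        vals[g].append(getattr(s, metric))
        both[g]["rsa_mean"].append(s.rsa_mean)
        both[g]["auc"].append(s.auc)
    g1 = np.asarray(vals[GROUP_REGULAR_DEEP], dtype=float)
    g2 = np.asarray(vals[GROUP_IRREGULAR_SHALLOW], dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 subjects")

    res = stats.mannwhitneyu(g2, g1, alternative="two-sided")
    p = float(res.pvalue)
    if not np.isfinite(p):  # fully tied samples: no evidence against the null
        p = 1.0
    mean1 = float(np.mean(g1))
    ratio = float(np.mean(g2) / mean1) if mean1 != 0 else float("inf")
    return GroupComparison(
        metric=metric,
        n={1: g1.size, 2: g2.size},
        means={
            g: {k: float(np.mean(v)) for k, v in both[g].items()} for g in (1, 2)
        },
        ses={
            g: {k: _se(np.asarray(v, dtype=float)) for k, v in both[g].items()}
            for g in (1, 2)
        },
        statistic=float(res.statistic),
        p_value=min(p, 1.0),
        ratio_of_means=ratio,
    )


@dataclass
class KappaResult:
    """Cohen's (weighted) kappa with its contingency table.

    ``kappa`` is NaN when agreement is undefined — both raters used one and
    the same single category, so expected disagreement is zero.
    """

    kappa: float
    weight_scheme: str
    contingency: np.ndarray
    observed_agreement: float
    expected_agreement: float
    categories: tuple = ()

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.kappa))


_SCHEMES = ("unweighted", "linear", "quadratic")


def _disagreement_weights(k: int, scheme: str) -> np.ndarray:
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if scheme == "unweighted":
        return (i != j).astype(float)
    if scheme == "linear":
        return np.abs(i - j) / (k - 1)
    if scheme == "quadratic":
        return ((i - j) / (k - 1)) ** 2
    raise ValueError(f"scheme must be one of {_SCHEMES}")


def weighted_kappa(
    ratings_1: Sequence,
    ratings_2: Sequence,
    scheme: str = "linear",
    categories: Optional[Sequence] = None,
) -> KappaResult:
    """Chance-corrected interrater agreement for ordered categories.

    ``categories`` fixes the ordered category set (defaults to the sorted
    union of the observed labels). With two categories the linear-weighted
    kappa coincides exactly with the unweighted (Cohen's) kappa.
    """
    r1, r2 = list(ratings_1), list(ratings_2)
    if len(r1) != len(r2):
        raise ValueError("rating vectors must have equal length")
    if not r1:
        raise ValueError("empty rating vectors")
    if scheme not in _SCHEMES:
        raise ValueError(f"scheme must be one of {_SCHEMES}")

    cats = list(categories) if categories is not None else sorted(set(r1) | set(r2))
    index = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    table = np.zeros((k, k))
    for a, b in zip(r1, r2):
        table[index[a], index[b]] += 1
    n = table.sum()
    o = table / n
    e = np.outer(o.sum(axis=1), o.sum(axis=0))
    observed_agreement = float(np.trace(o))
    expected_agreement = float(np.trace(e))

    if k == 1:
        # both raters confined to one identical category: kappa undefined
        return KappaResult(
            kappa=float("nan"),
            weight_scheme=scheme,
            contingency=table,
            observed_agreement=observed_agreement,
            expected_agreement=expected_agreement,
            categories=tuple(cats),
        )
    w = _disagreement_weights(k, scheme)
    denom = float(np.sum(w * e))
    if denom == 0.0:
        kappa = float("nan")
    else:
        kappa = 1.0 - float(np.sum(w * o)) / denom
    return KappaResult(
        kappa=kappa,
        weight_scheme=scheme,
        contingency=table,
        observed_agreement=observed_agreement,
        expected_agreement=expected_agreement,
        categories=tuple(cats),
    )


def percent_agreement(ratings_1: Sequence, ratings_2: Sequence) -> float:
    """Fraction of exactly matching paired ratings."""
    r1, r2 = list(ratings_1), list(ratings_2)
    if len(r1) != len(r2):
        raise ValueError("rating vectors must have equal length")
    if not r1:
        raise ValueError("empty rating vectors")
    return float(np.mean([a == b for a, b in zip(r1, r2)]))


def paired_ratings(observations: Sequence[ObservationRecord]):
    """Split a two-rater observation list into aligned rating vectors.

    Subjects observed by both raters are paired in subject order; subjects
    with a single rater are skipped.
    """
    by_subject: dict = defaultdict(dict)
    for obs in observations:
        by_subject[obs.subject_id][obs.rater_id] = obs.pattern
    r1, r2 = [], []
    for subject_id in sorted(by_subject):
        raters = by_subject[subject_id]
        if len(raters) < 2:
            continue
        ids = sorted(raters)
        r1.append(raters[ids[0]])
        r2.append(raters[ids[1]])
    return r1, r2
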