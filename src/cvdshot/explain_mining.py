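"""Mining color words out of prediction explanations.

Explanations are partitioned into a RED group (red mentioned, regardless of
pink), a PINK group (pink mentioned without red) and NEITHER.  For each
group the per-replicate percentage of melanoma predictions is computed, and
groups are compared with a two-tailed two-sample t-test (Welch by default).
Matching is stem-token based, not substring: "infrared" is not a red
mention, while hyphenated compounds ("red-brown") split and do count.
Negated mentions ("no red areas") count as mentions — a documented
simplification.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from cvdshot.color_sim import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ColorMentionGroup",
    "ExplanationGroupRates",
    "GroupComparison",
    "RED_WORDS",
    "PINK_WORDS",
    "classify_mention",
    "group_rates",
    "compare_groups",
    "permutation_pvalue",
]

#: Default stem-token lists; configurable per call for other lexicons.
RED_WORDS = frozenset({"red", "reds", "redder", "reddest", "reddish"})
PINK_WORDS = frozenset({"pink", "pinks", "pinker", "pinkest", "pinkish"})

_SCOREABLE = ("clean", "recovered")


class ColorMentionGroup(str, enum.Enum):
    RED = "RED"
    PINK = "PINK"
    NEITHER = "NEITHER"


def classify_mention(
    explanation: str,
    red_words: frozenset = RED_WORDS,
    pink_words: frozenset = PINK_WORDS,
) -> ColorMentionGroup:
    """Assign one explanation to RED, PINK or NEITHER.

    Tokenization is case-insensitive on non-letter boundaries, so hyphens
    split compounds.  A red token wins regardless of pink tokens; pink
    without red is PINK; otherwise NEITHER.  An empty string logs a warning
    and maps to NEITHER.
    """
    if not explanation:
        logger.warning("empty explanation classified as NEITHER")
        return ColorMentionGroup.NEITHER
    tokens = re.findall(r"[a-zA-Z]+", explanation.lower())
    if any(token in red_words for token in tokens):
        return ColorMentionGroup.RED
    if any(token in pink_words for token in tokens):
        return ColorMentionGroup.PINK
    return ColorMentionGroup.NEITHER


@dataclass
class ExplanationGroupRates:
    """Per-replicate melanoma-prediction percentages for one mention group.

    ``rates[i]`` is 100 x (melanoma predictions / group members) in
    replicate ``replicates[i]``; replicates where the group is empty are
    *missing* (absent from the lists), never imputed as zero.
    """

    group: ColorMentionGroup
    replicates: List[int] = field(default_factory=list)
    rates: List[float] = field(default_factory=list)
    counts: List[int] = field(default_factory=list)


def group_rates(
    predictions: Iterable[dict],
    red_words: frozenset = RED_WORDS,
    pink_words: frozenset = PINK_WORDS,
) -> Dict[ColorMentionGroup, ExplanationGroupRates]:
    """Per-group, per-replicate melanoma-prediction percentages.

    ``predictions`` are experiment log records (dicts with ``replicate``,
    ``predicted_label``, ``explanation``, ``parse_status``); only
    parse-clean/recovered records are scored.  Group sizes per replicate sum
    to the scoreable records of that replicate.
    """
    tallies: Dict[Tuple[ColorMentionGroup, int], List[int]] = {}
    any_scoreable = False
    for record in predictions:
        if record.get("parse_status") not in _SCOREABLE:
            continue
        any_scoreable = True
        group = classify_mention(record.get("explanation") or "",
                                 red_words, pink_words)
        key = (group, int(record["replicate"]))
        melanoma = 1 if record.get("predicted_label") == "melanoma" else 0
        tallies.setdefault(key, []).append(melanoma)
    if not any_scoreable:
        logger.warning("no scoreable predictions to mine")
        return {}
    out: Dict[ColorMentionGroup, ExplanationGroupRates] = {}
    for group in ColorMentionGroup:
        rates = ExplanationGroupRates(group=group)
        for (g, replicate), flags in sorted(
            tallies.items(), key=lambda kv: kv[0][1]
        ):
            if g is not group:
                continue
            rates.replicates.append(replicate)
            rates.rates.append(100.0 * sum(flags) / len(flags))
            rates.counts.append(len(flags))
        if rates.replicates:
            out[group] = rates
    return out


@dataclass
class GroupComparison:
    group_a: ExplanationGroupRates
    group_b: ExplanationGroupRates
    t_statistic: float
    p_value: float
    df: float
    zero_variance: bool = False


def compare_groups(
    a: ExplanationGroupRates,
    b: ExplanationGroupRates,
    equal_var: bool = False,
) -> GroupComparison:
    """Two-sample two-tailed t-test on per-replicate rates (Welch default).

    Degenerate policy: when both groups have zero variance, p is 1 for
    identical means and 0 otherwise, flagged via ``zero_variance``.
    """
    x = np.asarray(a.rates, dtype=np.float64)
    y = np.asarray(b.rates, dtype=np.float64)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError(
            "each group needs >= 2 non-missing replicate rates for a t-test"
        )
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        same = float(np.mean(x)) == float(np.mean(y))
        return GroupComparison(
            group_a=a, group_b=b,
            t_statistic=0.0 if same else float("inf") * np.sign(np.mean(x) - np.mean(y)),
            p_value=1.0 if same else 0.0,
            df=float(len(x) + len(y) - 2),
            zero_variance=True,
        )
    result = stats.ttest_ind(x, y, equal_var=equal_var)
    return GroupComparison(
        group_a=a, group_b=b,
        t_statistic=float(result.statistic),
        p_value=float(result.pvalue),
        df=float(result.df),
    )


def permutation_pvalue(
    a: Sequence[float],
    b: Sequence[float],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-tailed permutation p-value for the difference in group means.

    Monte-Carlo reference used to sanity-check the parametric t-test; counts
    the permutations whose absolute mean difference reaches the observed one
    (with the +1 correction for the identity permutation).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(a, dtype=np.float64)
    y = np.asarray(b, dtype=np.float64)
    pooled = np.concatenate([x, y])
    observed = abs(x.mean() - y.mean())
    n_a = len(x)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        diff = abs(perm[:n_a].mean() - perm[n_a:].mean())
        if diff >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)
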