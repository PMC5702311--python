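"""Standardisation, magnitude-based inference and training recommendations.

An effect (change in performance score for a +-1 SD change in training) is
standardised against the observed between-player SD of performance (~25
arbitrary units averaged over position groups) and labelled on the usual
standardised-magnitude scale (<0.2 trivial, 0.2-<0.6 small, 0.6-<1.2
moderate, 1.2-<2.0 large). Substantiveness is judged against the smallest
important change — 0.2 x between-player SD, i.e. +-5 raw units by default —
via the probabilities that the true effect lies beyond +-SIC under a shifted
t distribution recovered from the effect's 90% confidence limits. The
7-level probability qualifier scale (most unlikely ... most likely) follows
the non-clinical magnitude-based-inference framework; an effect is *unclear*
when both substantial directions remain plausible (both probabilities > 5%).

The training-recommendation mapping reproduces the reduce/no-change/increase
pattern a practitioner would derive from the +-1 SD effects; it is a
reconstruction of common practice, not a published rule (see the methods
note), and is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from scipy import stats

from loadperf.effect_model import EffectEstimate

MAGNITUDE_THRESHOLDS = ((0.2, "trivial"), (0.6, "small"), (1.2, "moderate"),
                        (2.0, "large"), (float("inf"), "very large"))

# upper bound of each probability bin -> qualifier
QUALIFIER_SCALE = ((0.005, "most unlikely"), (0.05, "very unlikely"),
                   (0.25, "unlikely"), (0.75, "possibly"), (0.95, "likely"),
                   (0.995, "very likely"), (1.0 + 1e-12, "most likely"))

QUALIFIER_SYMBOLS = {"possibly": "*", "likely": "**", "very likely": "***",
                     "most likely": "****"}


@dataclass(frozen=True)
class InferenceConfig:
    """Thresholds and scales of the magnitude-based-inference layer.

    ``between_sd_performance`` is the observed between-player SD of the
    performance score averaged over position groups; the smallest important
    change is 0.2 x that SD (5 raw units at the default 25). ``normal_df``
    is the df above which the normal approximation replaces the t tails.
    """

    between_sd_performance: float = 25.0
    sic_factor: float = 0.2
    unclear_threshold: float = 0.05
    normal_df: int = 100

    def __post_init__(self):
        if self.between_sd_performance <= 0:
            raise ValueError("between_sd_performance must be > 0")

    @property
    def smallest_important_change(self) -> float:
        return self.sic_factor * self.between_sd_performance


def standardize_and_classify(delta: float, between_sd: float,
                             cfg: InferenceConfig = InferenceConfig()) -> tuple[float, str]:
    """Standardise an effect and label its magnitude.

    Returns (delta / between_sd, label) with the label chosen by the
    absolute standardised value on the trivial/small/moderate/large bins.
    """
    if between_sd <= 0:
        raise ValueError(f"between_sd must be > 0, got {between_sd}")
    std = delta / between_sd
    for bound, label in MAGNITUDE_THRESHOLDS:
        if abs(std) < bound:
            return std, label
    return std, "very large"  # unreachable; inf bound catches all


def _tails(df: int, cfg: InferenceConfig):
    if df > cfg.normal_df:
        return stats.norm
    return stats.t(df)


def mbi_probabilities(delta: float, cl90: float, df: int,
                      cfg: InferenceConfig = InferenceConfig()
                      ) -> tuple[float, float, str, bool]:
    """Probabilities that the true effect is substantially positive/negative.

    The standard error is recovered from the 90% confidence limits
    (SE = cl90 / t_{0.95, df}); under the shifted t distribution,

    * p_substantial_pos = P(true effect > +SIC)
    * p_substantial_neg = P(true effect < -SIC)

    and the remaining mass is trivial, so the three probabilities sum to 1.
    The qualifier describes the larger substantial probability; the effect
    is *unclear* (clear = False) when both exceed 5%.
    """
    if cl90 <= 0:
        raise ValueError(f"cl90 must be > 0, got {cl90}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    dist = _tails(df, cfg)
    se = cl90 / dist.ppf(0.95)
    sic = cfg.smallest_important_change
    p_pos = float(dist.sf((sic - delta) / se))
    p_neg = float(dist.cdf((-sic - delta) / se))
    clear = not (p_pos > cfg.unclear_threshold and p_neg > cfg.unclear_threshold)
    if not clear:
        qualifier = "unclear"
    else:
        qualifier = qualifier_for(max(p_pos, p_neg))
    return p_pos, p_neg, qualifier, clear


def p_trivial(delta: float, cl90: float, df: int,
              cfg: InferenceConfig = InferenceConfig()) -> float:
    """Probability the true effect lies within +-SIC (complements the two tails)."""
    dist = _tails(df, cfg)
    se = cl90 / dist.ppf(0.95)
    sic = cfg.smallest_important_change
    return float(dist.cdf((sic - delta) / se) - dist.cdf((-sic - delta) / se))


def qualifier_for(p: float) -> str:
    """Map a probability to its MBI qualifier word."""
    if not 0 <= p <= 1:
        raise ValueError(f"probability must be in [0, 1], got {p}")
    for bound, label in QUALIFIER_SCALE:
        if p < bound:
            return label
    return "most likely"


def qualifier_symbol(qualifier: str, direction: str = "positive") -> str:
    """Footnote code for a qualifier: '*'-codes for increases, '0'-codes for decreases."""
    base = QUALIFIER_SYMBOLS.get(qualifier, "")
    if not base:
        return ""
    return base if direction == "positive" else "0" * len(base)


def annotate_effect(effect: EffectEstimate,
                    cfg: InferenceConfig = InferenceConfig()) -> EffectEstimate:
    """Fill an effect estimate's standardised magnitude and MBI fields in place."""
    std, magnitude = standardize_and_classify(effect.delta,
                                              cfg.between_sd_performance, cfg)
    p_pos, p_neg, qualifier, clear = mbi_probabilities(
        effect.delta, effect.cl90, effect.df, cfg)
    effect.standardized = std
    effect.magnitude = magnitude
    effect.p_substantial_pos = p_pos
    effect.p_substantial_neg = p_neg
    effect.qualifier = qualifier
    effect.clear = clear
    return effect


def _clear_substantial(effect: EffectEstimate, direction: str,
                       cfg: InferenceConfig) -> bool:
    if effect.clear is None:
        raise ValueError("effect must be annotated (annotate_effect) first")
    p = (effect.p_substantial_pos if direction == "positive"
         else effect.p_substantial_neg)
    # at least "possibly" substantial in that direction, and not unclear
    return bool(effect.clear and p >= 0.25)


def recommend_training(effect_minus1: EffectEstimate, effect_plus1: EffectEstimate,
                       cfg: InferenceConfig = InferenceConfig()) -> str:
    """Deterministic training recommendation from the +-1 SD effects.

    * clear decrement above the mean and clear benefit below it ->
      "Reduce by >1 SD";
    * clear decrement above the mean only -> "Reduce by 0 to ~1 SD" when the
      -1 SD point estimate is positive, else "Reduce by ~1 SD";
    * clear benefit above the mean -> "Increase by ~1 SD";
    * otherwise -> "No change".
    """
    if effect_minus1 is None or effect_plus1 is None:
        raise ValueError("both +-1 SD effects are required")
    decrement_high = _clear_substantial(effect_plus1, "negative", cfg)
    benefit_low = _clear_substantial(effect_minus1, "positive", cfg)
    benefit_high = _clear_substantial(effect_plus1, "positive", cfg)
    if decrement_high and benefit_low:
        return "Reduce by >1 SD"
    if decrement_high:
        return "Reduce by 0 to ~1 SD" if effect_minus1.delta > 0 else "Reduce by ~1 SD"
    if benefit_high:
        return "Increase by ~1 SD"
    return "No change"
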