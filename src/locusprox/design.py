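"""Experimental design: TMT channel assignments and run configuration.

A proximity-labeling TMT experiment multiplexes several biological
conditions into one MS run.  The design map records which TMT reporter
channel carries which condition and biological replicate.  The default
design reproduces the randomized 18-plex layout used for the promoter
pulldown experiment: three promoter-tiling guide RNAs (g1/g2/g3) times
three biological replicates, two negative controls in triplicate
(NoG+ = untargeted labeling background, NoG- = no-labeling bead and
endogenous-biotin background), one pooled-sample reference channel, and
two empty channels.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Iterable, Optional

import yaml


class Condition(str, enum.Enum):
    """Biological condition carried by a TMT channel."""

    G1 = "g1"
    G2 = "g2"
    G3 = "g3"
    NOG_PLUS = "NoGplus"
    NOG_MINUS = "NoGminus"
    POOL = "pool"
    EMPTY = "empty"


#: Guide-RNA conditions targeting the promoter.
ON_TARGET_CONDITIONS = (Condition.G1, Condition.G2, Condition.G3)
#: Conditions in which proximity labeling occurred (targeted or not).
LABELING_CONDITIONS = ON_TARGET_CONDITIONS + (Condition.NOG_PLUS,)


@dataclasses.dataclass(frozen=True)
class ChannelAssignment:
    channel_label: str
    condition: Condition
    bio_replicate: Optional[int] = None  # None for pool / empty channels

    def __post_init__(self) -> None:
        if self.condition in (Condition.POOL, Condition.EMPTY):
            if self.bio_replicate is not None:
                raise ValueError(
                    f"channel {self.channel_label!r}: {self.condition.value} "
                    "channels carry no biological replicate"
                )
        elif self.bio_replicate is None or self.bio_replicate < 1:
            raise ValueError(
                f"channel {self.channel_label!r}: biological replicate must be "
                "a positive integer"
            )


@dataclasses.dataclass(frozen=True)
class DesignMap:
    """Channel -> (condition, biological replicate) assignment."""

    assignments: tuple[ChannelAssignment, ...]

    def __post_init__(self) -> None:
        labels = [a.channel_label for a in self.assignments]
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate channel labels in design: {dup}")

    @property
    def channels(self) -> list[str]:
        """All non-empty channel labels, in design order."""
        return [
            a.channel_label
            for a in self.assignments
            if a.condition is not Condition.EMPTY
        ]

    @property
    def sample_channels(self) -> list[str]:
        """Channels carrying an actual sample (not pool, not empty)."""
        return [
            a.channel_label
            for a in self.assignments
            if a.condition not in (Condition.POOL, Condition.EMPTY)
        ]

    def channels_for(self, *conditions: Condition) -> list[str]:
        wanted = set(conditions)
        return [
            a.channel_label for a in self.assignments if a.condition in wanted
        ]

    def assignment(self, channel_label: str) -> ChannelAssignment:
        for a in self.assignments:
            if a.channel_label == channel_label:
                return a
        raise KeyError(channel_label)

    @property
    def on_target_channels(self) -> list[str]:
        return self.channels_for(*ON_TARGET_CONDITIONS)

    @property
    def labeling_channels(self) -> list[str]:
        return self.channels_for(*LABELING_CONDITIONS)


def default_design() -> DesignMap:
    """The randomized TMTpro 18-plex scheme of the promoter pulldown run.

    16 used channels: 3 gRNAs x 3 biological replicates, NoG+ x3, NoG- x3,
    one sample pool; plus two empty channels.
    """
    scheme = [
        ("126", Condition.G2, 1),
        ("127N", Condition.G2, 2),
        ("127C", Condition.G1, 3),
        ("128N", Condition.G1, 1),
        ("128C", Condition.NOG_PLUS, 3),
        ("129N", Condition.NOG_PLUS, 1),
        ("129C", Condition.NOG_MINUS, 1),
        ("130N", Condition.EMPTY, None),
        ("130C", Condition.NOG_PLUS, 2),
        ("131N", Condition.NOG_MINUS, 2),
        ("131C", Condition.G3, 3),
        ("132N", Condition.G3, 1),
        ("132C", Condition.G3, 2),
        ("133N", Condition.POOL, None),
        ("133C", Condition.G1, 2),
        ("134N", Condition.NOG_MINUS, 3),
        ("134C", Condition.G2, 3),
        ("135N", Condition.EMPTY, None),
    ]
    return DesignMap(
        tuple(ChannelAssignment(c, cond, rep) for c, cond, rep in scheme)
    )


class SemPoolingRule(str, enum.Enum):
    """How the pooled on-target SEM is formed.

    ``per_channel_values`` pools all contributing gRNA channel values
    (up to 9); ``per_gRNA_means`` first averages biological replicates
    within each gRNA, then takes mean/SEM over the (up to 3) gRNA means.
    """

    PER_CHANNEL_VALUES = "per_channel_values"
    PER_GRNA_MEANS = "per_gRNA_means"


class TTestVariant(str, enum.Enum):
    WELCH = "welch"
    POOLED = "pooled"


@dataclasses.dataclass
class RunConfig:
    """Tunable analysis parameters.

    fc_threshold : linear fold-change cut for both the contaminant and
        the enrichment call (default 1.2, the smallest ratio isobaric
        quantification resolves reliably).
    alpha : significance level for adjusted p / q values (default 0.05).
    lambda_pi0 : Storey tuning parameter; p-values above it are taken
        as draws from the null when estimating pi0 (default 0.4).
    """

    fc_threshold: float = 1.2
    alpha: float = 0.05
    lambda_pi0: float = 0.4
    sem_pooling_rule: SemPoolingRule = SemPoolingRule.PER_CHANNEL_VALUES
    ttest_variant: TTestVariant = TTestVariant.WELCH
    seed: int = 0

    def __post_init__(self) -> None:
        self.sem_pooling_rule = SemPoolingRule(self.sem_pooling_rule)
        self.ttest_variant = TTestVariant(self.ttest_variant)
        if not self.fc_threshold > 1:
            raise ValueError("fc_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.lambda_pi0 < 1:
            raise ValueError("lambda_pi0 must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["sem_pooling_rule"] = self.sem_pooling_rule.value
        payload["ttest_variant"] = self.ttest_variant.value
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
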