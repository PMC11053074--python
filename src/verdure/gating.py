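"""Gate decisions shared by the pipeline stages.

Every image entering the pipeline receives exactly one routing verdict per
stage: it passes on, or it is filtered (too blurry, or too little greenery in
frame) and a re-shoot is scheduled after a waiting period.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class GateOutcome(enum.Enum):
    PASS = "pass"
    FILTERED_BLUR = "filtered_blur"
    FILTERED_AREA = "filtered_area"


@dataclass
class GateDecision:
    """Routing verdict for one image at one gate.

    ``scores`` carries the stage-specific quantities that drove the decision
    (classifier clear-probability, greenery proportion) for logging.
    Filtered decisions carry the scheduled re-shoot time ``reshoot_at``
    (seconds, same clock as ``timestamp``).
    """

    outcome: GateOutcome
    scores: dict[str, float] = field(default_factory=dict)
    timestamp: float = 0.0
    reshoot_at: float | None = None

    def __post_init__(self):
        if self.outcome is GateOutcome.PASS and self.reshoot_at is not None:
            raise ValueError("a PASS decision cannot schedule a re-shoot")

    @property
    def passed(self) -> bool:
        return self.outcome is GateOutcome.PASS
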