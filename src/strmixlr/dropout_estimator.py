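"""Predict the drop-out probability from average detected peak height.

P(D_O) is sample-specific: low-template samples give short peaks and drop
out more.  Laboratories calibrate a logistic regression of drop-out against
the average height (RFU) of detected peaks on validation samples with known
drop-out, then apply it to casework.  The regression coefficients are
configuration — every typing system and laboratory should estimate its own —
so this module only applies a user-supplied model; it never fits one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

from .datamodel import LocusEvidence

_CLIP = 1e-6
_TRANSFORMS = ("identity", "log10")


@dataclass(frozen=True)
class LogisticModel:
    """Pre-fit logistic regression P(D_O) = logistic(intercept + slope*T(h)).

    ``covariate_transform`` must be stated explicitly ("identity" or "log10");
    published calibrations differ on whether the covariate is the raw or the
    log average peak height, so no default is applied silently.
    """

    intercept: float
    slope: float
    covariate_transform: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.covariate_transform not in _TRANSFORMS:
            raise ValueError(
                f"covariate_transform must be one of {_TRANSFORMS}, "
                f"got {self.covariate_transform!r}"
            )


def load_model(path: str | Path) -> LogisticModel:
    """Load a logistic model from its JSON file."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return LogisticModel(
        intercept=float(data["intercept"]),
        slope=float(data["slope"]),
        covariate_transform=data["covariate_transform"],
        note=str(data.get("note", "")),
    )


def average_peak_height(
    evidence: Mapping[str, LocusEvidence],
    markers: Optional[set[str]] = None,
) -> float:
    """Arithmetic mean peak height (RFU) over detected alleles.

    Raises if no heights are available: supply P(D_O) directly in that case.
    """
    heights: list[float] = []
    for marker, ev in evidence.items():
        if markers is not None and marker not in markers:
            continue
        if ev.heights:
            heights.extend(ev.heights[a] for a in ev.detected if a in ev.heights)
    if not heights:
        raise ValueError(
            "no peak heights available in the evidence profile; supply P(D_O) "
            "directly instead of predicting it from peak height"
        )
    return sum(heights) / len(heights)


def predict_dropout(model: LogisticModel, h: float) -> float:
    """P(D_O) from the logistic model at average peak height ``h`` (RFU),
    clipped away from 0 and 1 so downstream likelihoods stay positive."""
    if not (h > 0):
        raise ValueError("average peak height must be positive")
    x = math.log10(h) if model.covariate_transform == "log10" else h
    p = 1.0 / (1.0 + math.exp(-(model.intercept + model.slope * x)))
    return min(max(p, _CLIP), 1.0 - _CLIP)
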