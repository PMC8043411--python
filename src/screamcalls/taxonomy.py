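"""The fixed vocalization taxonomy: 6 scream types plus a neutral baseline.

Category order is canonical throughout the package (it defines deterministic
tie-breaking in classification and the ordering of enumerated category
splits). The alarm/non-alarm assignment below is the data-driven partition
of the 6 scream types that the perceptual analyses recover: pain, fear, and
anger screams are alarming; pleasure, sadness, and joy screams are not.
"""

from __future__ import annotations

NEUTRAL = "neutral"

# Canonical category order: neutral first, then the 6 scream types.
SCREAM_TYPES: tuple[str, ...] = (
    "neutral",
    "pleasure",
    "sadness",
    "joy",
    "pain",
    "fear",
    "anger",
)

NONNEUTRAL_TYPES: tuple[str, ...] = SCREAM_TYPES[1:]

ALARM_TYPES: frozenset[str] = frozenset({"pain", "fear", "anger"})
NONALARM_TYPES: frozenset[str] = frozenset({"pleasure", "sadness", "joy"})

# Default roughness bands of the temporal modulation axis (Hz): energy near
# 60 Hz and near 160 Hz characterizes rough, scream-like vocalizations.
LOW_ROUGHNESS_BAND: tuple[float, float] = (50.0, 70.0)
HIGH_ROUGHNESS_BAND: tuple[float, float] = (140.0, 180.0)


def type_index(scream_type: str) -> int:
    try:
        return SCREAM_TYPES.index(scream_type)
    except ValueError:
        raise ValueError(f"unknown scream type: {scream_type!r}") from None
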