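"""Controlled column vocabulary for per-cell index tables.

Sensor tags: ``c9`` (initiator caspase-9 probe, GFP/Alexa 532) and ``c3``
(executioner caspase-3 probe, RFP/Alexa 660). Times are in seconds,
amplitudes in normalized-ratio units.
"""

SENSOR_TAGS = ("c9", "c3")

SENSOR_INDEX_NAMES = (
    "initiation",
    "saturation",
    "duration",
    "response_scale",
    "maximum_ratio",
    "slope",
    "integration",
    "time_at_max",
)

INTERVAL_COLUMNS = ("promotion_interval", "activation_interval", "completion_interval")

#: Full, ordered column vocabulary of the population table.
INDEX_COLUMNS = tuple(
    f"{name}_{tag}" for tag in SENSOR_TAGS for name in SENSOR_INDEX_NAMES
) + INTERVAL_COLUMNS
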