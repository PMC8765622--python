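"""Small reference datasets.

``PUBLISHED_ZONE_AREAS_KM2`` is the published quantification of cocoa
climate-adaptation zones for the Brazilian Amazon biome (area in km² per
zone for the current climate and the two mid-century emissions
scenarios), the table whose presentation conventions this package's
reporting stage reproduces. Feeding it through
:class:`~cocoazone.reporting.ZoneTable` and
:func:`~cocoazone.reporting.derived_change_stats` replays every percent
and derived change statistic quoted alongside it.
"""

PUBLISHED_ZONE_AREAS_KM2: dict[str, dict[str, float]] = {
    "current": {
        "conversion": 1597.95,
        "diversification": 4391.77,
        "expansion": 532394.94,
        "intensification": 73834.26,
        "not_recommended": 131843.07,
    },
    "RCP4.5": {
        "conversion": 15505.92,
        "diversification": 46419.80,
        "expansion": 279644.67,
        "intensification": 53157.47,
        "not_recommended": 349334.13,
    },
    "RCP8.5": {
        "conversion": 56593.59,
        "diversification": 64436.06,
        "expansion": 129174.18,
        "intensification": 21657.23,
        "not_recommended": 472200.93,
    },
}

PUBLISHED_TOTAL_KM2 = 744061.99
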