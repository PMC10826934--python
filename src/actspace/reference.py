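"""Published reference contingency counts for EMA–GPS concordance.

These are the printed 2×2 counts from a published urban/non-urban
smartphone activity-space validation study (162 participants, 7 days,
3 EMAs/day): EMA-reported location cross-tabulated against GPS-derived
at-home status at 20 / 50 / 100 m home-footprint buffers, reported
separately for residence strata (urban, non-urban) and device strata
(android, ios). They serve as fixed benchmark inputs for reproducing the
study's column percentages and agreement bounds; the package never fits
anything to them.

Structure: ``REFERENCE_CONCORDANCE_COUNTS[(buffer, stratum)]`` maps to
``(at_home_col, not_home_col)`` where each column is
``(GPS at-home count, GPS not-home count)`` for that EMA answer.
"""

from __future__ import annotations

from .ema import ConcordanceTable

__all__ = [
    "REFERENCE_CONCORDANCE_COUNTS",
    "REFERENCE_NOT_MATCHED",
    "reference_tables",
]

REFERENCE_CONCORDANCE_COUNTS: dict[tuple[int, str], tuple[tuple[int, int], tuple[int, int]]] = {
    (20, "urban"): ((927, 107), (91, 569)),
    (50, "urban"): ((966, 68), (101, 559)),
    (100, "urban"): ((974, 60), (103, 557)),
    (20, "non_urban"): ((286, 63), (29, 232)),
    (50, "non_urban"): ((319, 30), (34, 227)),
    (100, "non_urban"): ((342, 7), (35, 226)),
    (20, "android"): ((506, 93), (36, 305)),
    (50, "android"): ((551, 48), (43, 298)),
    (100, "android"): ((564, 35), (45, 296)),
    (20, "ios"): ((707, 77), (84, 496)),
    (50, "ios"): ((734, 50), (92, 488)),
    (100, "ios"): ((752, 32), (93, 487)),
}

# unmatched EMA observations per stratum (EMA at-home + EMA not-home)
REFERENCE_NOT_MATCHED: dict[str, int] = {
    "urban": 255 + 184,
    "non_urban": 75 + 78,
    "android": 104 + 58,
    "ios": 226 + 204,
}


def reference_tables() -> list[ConcordanceTable]:
    """The benchmark counts as ConcordanceTable objects (percentages are
    computed, not stored)."""
    return [
        ConcordanceTable.from_counts(
            buffer=buf,
            stratum=stratum,
            at_home_col=at_home_col,
            not_home_col=not_home_col,
            n_not_matched=REFERENCE_NOT_MATCHED[stratum],
        )
        for (buf, stratum), (at_home_col, not_home_col) in REFERENCE_CONCORDANCE_COUNTS.items()
    ]
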