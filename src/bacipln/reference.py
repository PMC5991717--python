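"""Published difference estimates for the six-lake monitoring study.

The long-term gill-net monitoring analysis of the Rainy-Namakan reservoir
complex reported, for each of six northern Minnesota lakes and three
species, the posterior difference in mean catch per gill-net set between
the Pre-2000 (1990-1999) and Post-2005 (2005-2014) periods with
equal-tailed 95% credible intervals.  Those reported estimates are
embedded here so the credible-interval decision rules can be exercised
(and the published classification reproduced) without access to the raw
deposited survey workbook.

Units are fish per gill-net set; positive differences are increases after
the 2000 water-level management change.
"""

from __future__ import annotations

from .baci import DifferenceSummary
from .data_io import DEFAULT_ROLES

__all__ = ["PUBLISHED_DIFFERENCES", "published_summaries"]

#: (lake, species, posterior mean difference, 95% CrI low, 95% CrI high)
PUBLISHED_DIFFERENCES: list[tuple[str, str, float, float, float]] = [
    ("Lake of the Woods", "Walleye", 4.24, 3.12, 5.34),
    ("Lake Vermilion", "Walleye", 2.35, 0.68, 4.01),
    ("Lake Kabetogama", "Walleye", -0.13, -1.32, 0.97),
    ("Namakan Lake", "Walleye", 0.88, -0.37, 2.11),
    ("Rainy Lake", "Walleye", 2.09, 1.30, 2.87),
    ("Sand Point Lake", "Walleye", 0.58, -1.08, 2.31),
    ("Lake of the Woods", "Northern Pike", 0.94, 0.76, 1.11),
    ("Lake Vermilion", "Northern Pike", -0.36, -0.60, -0.13),
    ("Lake Kabetogama", "Northern Pike", 0.66, 0.26, 1.06),
    ("Namakan Lake", "Northern Pike", 0.86, 0.46, 1.27),
    ("Rainy Lake", "Northern Pike", 0.48, 0.17, 0.81),
    ("Sand Point Lake", "Northern Pike", 0.94, 0.45, 1.44),
    ("Lake of the Woods", "Yellow Perch", -0.51, -1.63, 0.62),
    ("Lake Vermilion", "Yellow Perch", -5.85, -9.50, -2.26),
    ("Lake Kabetogama", "Yellow Perch", 4.23, 2.93, 5.57),
    ("Namakan Lake", "Yellow Perch", -0.10, -0.77, 0.58),
    ("Rainy Lake", "Yellow Perch", 0.68, -0.13, 1.62),
    ("Sand Point Lake", "Yellow Perch", -0.86, -1.52, -0.27),
]


def published_summaries() -> list[DifferenceSummary]:
    """The published estimates as :class:`DifferenceSummary` rows."""
    return [
        DifferenceSummary(
            lake=lake,
            species=sp,
            post_mean=mean,
            ci_low=lo,
            ci_high=hi,
            role=DEFAULT_ROLES[lake],
        )
        for lake, sp, mean, lo, hi in PUBLISHED_DIFFERENCES
    ]
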