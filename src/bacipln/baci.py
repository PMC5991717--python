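"""Before-after differences and control-vs-impact decision rules.

For each lake x species, the before-after effect is the posterior of
D = M_post - M_pre (fish per gill-net set), formed by pairing the two
independent period posteriors draw-by-draw.  The BACI decision then
compares impact lakes against control lakes pairwise: an impact lake's
change is *distinct-from-all-controls* when its 95% credible interval for
D overlaps no control lake's interval; otherwise it is
consistent-with-some-control.  Intervals are closed, so touching
endpoints count as overlap and an interval endpoint exactly at zero does
not exclude zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .plnorm import PosteriorSamples

logger = logging.getLogger(__name__)

__all__ = [
    "BaciReport",
    "DifferenceSummary",
    "classify_baci",
    "credible_interval",
    "difference_posterior",
    "excludes_zero",
    "intervals_overlap",
    "render_table",
]


@dataclass
class DifferenceSummary:
    """Posterior summary of the before-after difference for one lake x species."""

    lake: str
    species: str
    post_mean: float
    ci_low: float
    ci_high: float
    prob_positive: float | None = None
    draws: np.ndarray | None = None
    role: str | None = None

    @property
    def interval(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


@dataclass
class BaciReport:
    """Per-row flags and verdicts plus the pairwise overlap matrices.

    ``rows`` is a list of dicts (lake, species, role, post_mean, ci_low,
    ci_high, excludes_zero, overlaps: {control lake -> bool}, verdict).
    Verdicts: ``control`` for control-lake rows, else
    ``distinct-from-all-controls`` / ``consistent-with-some-control`` /
    ``indeterminate`` (no control fit available).  ``overlap_matrix`` maps
    species -> {(lake_a, lake_b) -> bool} over every lake pair.
    """

    rows: list[dict] = field(default_factory=list)
    overlap_matrix: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def row(self, lake: str, species: str) -> dict:
        for r in self.rows:
            if r["lake"] == lake and r["species"] == species:
                return r
        raise KeyError((lake, species))


def credible_interval(draws: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval from posterior draws.

    Percentiles are computed with linear interpolation between order
    statistics (numpy's default convention).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot form a credible interval from zero draws")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be inside (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def excludes_zero(interval: tuple[float, float]) -> bool:
    """True iff the closed interval lies strictly on one side of zero."""
    lo, hi = interval
    if lo > hi:
        raise ValueError("interval must satisfy low <= high")
    return lo > 0.0 or hi < 0.0


def intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """True iff two closed intervals intersect (touching endpoints overlap)."""
    if a[0] > a[1] or b[0] > b[1]:
        raise ValueError("interval must satisfy low <= high")
    return a[0] <= b[1] and b[0] <= a[1]


def difference_posterior(
    post: PosteriorSamples,
    pre: PosteriorSamples,
    lake: str = "",
    species: str = "",
    level: float = 0.95,
    role: str | None = None,
) -> DifferenceSummary:
    """Posterior of D = M_post - M_pre by draw-index pairing.

    The period fits are independent, so any pairing of draws is
    statistically equivalent; pairing by retained-draw index (after
    truncating to the shorter run) keeps the result reproducible.
    """
    n = min(len(post), len(pre))
    if n == 0:
        raise ValueError("no overlapping draws between the period posteriors")
    d = post.mean_draws[:n] - pre.mean_draws[:n]
    lo, hi = credible_interval(d, level)
    return DifferenceSummary(
        lake=lake,
        species=species,
        post_mean=float(d.mean()),
        ci_low=lo,
        ci_high=hi,
        prob_positive=float(np.mean(d > 0)),
        draws=d,
        role=role,
    )


def classify_baci(
    summaries: Sequence[DifferenceSummary],
    roles: Mapping[str, str],
) -> BaciReport:
    """Apply the credible-interval-overlap decision rule per species.

    Each impact lake's difference interval is compared with every control
    lake's; the verdict is distinct-from-all-controls iff no control
    interval overlaps.  Control rows carry the ``control`` verdict.  A
    species with no fitted control lake yields ``indeterminate`` impact
    rows and a warning.
    """
    report = BaciReport()
    species_list = sorted({s.species for s in summaries})
    for sp in species_list:
        rows_sp = [s for s in summaries if s.species == sp]
        controls = [s for s in rows_sp if roles.get(s.lake) == "control"]
        lakes = [s.lake for s in rows_sp]
        matrix = {
            (a.lake, b.lake): intervals_overlap(a.interval, b.interval)
            for a in rows_sp
            for b in rows_sp
        }
        report.overlap_matrix[sp] = matrix
        if not controls:
            logger.warning("species %s has no control-lake fit; verdicts indeterminate", sp)
        # controls first, then impacts, alphabetical within each
        ordered = sorted(rows_sp, key=lambda s: (roles.get(s.lake) != "control", s.lake))
        for s in ordered:
            role = roles.get(s.lake, s.role or "impact")
            overlaps = {
                c.lake: intervals_overlap(s.interval, c.interval)
                for c in controls
                if c.lake != s.lake
            }
            if role == "control":
                verdict = "control"
            elif not controls:
                verdict = "indeterminate"
            elif not any(overlaps.values()):
                verdict = "distinct-from-all-controls"
            else:
                verdict = "consistent-with-some-control"
            report.rows.append(
                {
                    "lake": s.lake,
                    "species": sp,
                    "role": role,
                    "post_mean": s.post_mean,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                    "prob_positive": s.prob_positive,
                    "excludes_zero": excludes_zero(s.interval),
                    "overlaps": overlaps,
                    "verdict": verdict,
                }
            )
        if not rows_sp:
            logger.info("species %s has no rows; omitted", sp)
    return report


def render_table(report: BaciReport, fmt: str = "tsv") -> str:
    """Render the report species-major, controls first, 2-decimal rounding.

    Differences use round-half-even formatting; rows whose interval
    excludes zero are marked with ``*`` (TSV) or bold (markdown).
    """
    if not report.rows:
        raise ValueError("cannot render an empty report")
    if fmt not in {"tsv", "markdown"}:
        raise ValueError(f"unknown table format {fmt!r}")
    header = ["Lake", "Species", "Difference (95% CrI)", "Verdict"]
    lines = []
    if fmt == "markdown":
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "|".join("---" for _ in header) + "|")
    else:
        lines.append("\t".join(header))
    for r in report.rows:
        cell = f"{r['post_mean']:.2f} ({r['ci_low']:.2f} to {r['ci_high']:.2f})"
        lake = r["lake"] + ("^C" if r["role"] == "control" else "")
        if r["excludes_zero"]:
            cell = f"**{cell}**" if fmt == "markdown" else cell + " *"
        fields = [lake, r["species"], cell, r["verdict"]]
        if fmt == "markdown":
            lines.append("| " + " | ".join(fields) + " |")
        else:
            lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"
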