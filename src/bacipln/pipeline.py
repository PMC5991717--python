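"""End-to-end driver: read -> filter -> fit -> difference -> classify.

:func:`run_pipeline` executes the full analysis from a :class:`RunConfig`
and writes every artifact (canonical CSV, filter log, per-group posterior
draws, diagnostics JSON, a Table-1-style TSV and a JSON report).  Each
artifact embeds the package version, the seed and a hash of the resolved
configuration, so a run is fully reproducible from (input, config).
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import baci, data_io, plnorm

logger = logging.getLogger(__name__)

__all__ = ["ConvergenceError", "RunConfig", "fit_groups", "run_pipeline"]


class ConvergenceError(RuntimeError):
    """One or more group fits failed the PSRF <= 1.05 gate."""


def _version() -> str:
    try:
        return _pkg_version("bacipln")
    except Exception:  # pragma: no cover - not installed
        return "unknown"


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    ``schema`` maps canonical column names to source columns; ``roles``
    maps lakes to control/impact; ``exclusions`` is a list of
    (lake, (year_lo, year_hi)).  The seed expands into one substream per
    lake x species x period group, so adding a group does not perturb the
    draws of another.
    """

    input: str
    outdir: str = "bacipln_run"
    schema: dict = field(default_factory=dict)
    roles: dict = field(default_factory=lambda: dict(data_io.DEFAULT_ROLES))
    exclusions: list = field(default_factory=lambda: list(data_io.DEFAULT_EXCLUSIONS))
    periods: data_io.PeriodDefinition = field(default_factory=data_io.PeriodDefinition)
    station_mode: str = "strict"
    priors: plnorm.Priors = field(default_factory=plnorm.Priors)
    mcmc: plnorm.McmcConfig = field(default_factory=plnorm.McmcConfig)
    seed: int | None = None
    mean_kind: str = "population"
    allow_unconverged: bool = False
    sheet: int | str = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update(overrides)
        if "periods" in doc and not isinstance(doc["periods"], data_io.PeriodDefinition):
            p = doc["periods"]
            doc["periods"] = data_io.PeriodDefinition(tuple(p["before"]), tuple(p["after"]))
        if "priors" in doc and not isinstance(doc["priors"], plnorm.Priors):
            doc["priors"] = plnorm.Priors(**doc["priors"])
        if "mcmc" in doc and not isinstance(doc["mcmc"], plnorm.McmcConfig):
            doc["mcmc"] = plnorm.McmcConfig(**doc["mcmc"])
        if "exclusions" in doc:
            doc["exclusions"] = [(l, (int(y0), int(y1))) for l, (y0, y1) in doc["exclusions"]]
        return cls(**doc)

    def resolved_seed(self) -> int:
        return self.mcmc.seed if self.seed is None else int(self.seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["periods"] = {"before": list(self.periods.before), "after": list(self.periods.after)}
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(json.loads(json.dumps(self.to_dict(), default=str)), sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _group_seed(base_seed: int, lake: str, species: str, period: str) -> int:
    """Stable per-group seed below 2^31."""
    key = zlib.crc32(f"{lake}|{species}|{period}".encode())
    return (int(base_seed) * 1_000_003 + key) % (2**31 - 1)


def fit_groups(
    table: data_io.CatchTable,
    priors: plnorm.Priors,
    config: plnorm.McmcConfig,
    base_seed: int,
    mean_kind: str = "population",
) -> dict[tuple[str, str, str], plnorm.PosteriorSamples]:
    """Fit every lake x species x period group with >= 2 gill-net sets."""
    from dataclasses import replace

    fits: dict[tuple[str, str, str], plnorm.PosteriorSamples] = {}
    for (lake, sp, period), sub in table.records.groupby(["lake", "species", "period"]):
        counts = sub["count"].to_numpy(int)
        if counts.size < 2:
            logger.warning("group %s has <2 sets; skipped", (lake, sp, period))
            continue
        cfg = replace(config, seed=_group_seed(base_seed, lake, sp, period))
        fits[(lake, sp, period)] = plnorm.fit_group(counts, priors, cfg, mean_kind=mean_kind)
    return fits


def difference_summaries(
    fits: Mapping[tuple[str, str, str], plnorm.PosteriorSamples],
    roles: Mapping[str, str],
) -> list[baci.DifferenceSummary]:
    """Before-after difference posterior per lake x species with both fits."""
    summaries = []
    pairs = sorted({(lake, sp) for (lake, sp, _p) in fits})
    for lake, sp in pairs:
        pre = fits.get((lake, sp, "pre"))
        post = fits.get((lake, sp, "post"))
        if pre is None or post is None:
            logger.warning("lake %s species %s missing a period fit; skipped", lake, sp)
            continue
        summaries.append(
            baci.difference_posterior(post, pre, lake=lake, species=sp, role=roles.get(lake))
        )
    return summaries


def run_pipeline(config: RunConfig) -> baci.BaciReport:
    """Execute the full BACI analysis and write all artifacts.

    Raises :class:`ConvergenceError` after writing artifacts if any group
    fit has PSRF > 1.05 and ``allow_unconverged`` is False.
    """
    outdir = Path(config.outdir)
    seed = config.resolved_seed()

    table = data_io.read_catch_table(config.input, config.schema, config.roles, config.sheet)
    plan = data_io.plan_station_filter(
        table, config.station_mode, config.exclusions, periods=config.periods
    )
    table = data_io.apply_lake_exclusions(table, config.exclusions)
    table = data_io.filter_consistent_stations(table, config.station_mode, plan=plan)
    table = data_io.assign_periods(table, config.periods)

    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {
        "package_version": _version(),
        "seed": seed,
        "config_hash": config.config_hash(),
        "priors": asdict(config.priors),
        "interval_convention": "equal-tailed, linear interpolation between order statistics",
    }
    data_io.write_canonical_csv(table, outdir / "canonical.csv", outdir / "filter_log.txt")

    fits = fit_groups(table, config.priors, config.mcmc, seed, config.mean_kind)
    draws_dir = outdir / "posteriors"
    draws_dir.mkdir(exist_ok=True)
    diagnostics = {}
    unconverged = []
    for (lake, sp, period), ps in fits.items():
        slug = f"{lake}_{sp}_{period}".replace(" ", "-")
        ps.to_frame().to_csv(draws_dir / f"{slug}.csv", index=False)
        diag = {k: v for k, v in ps.diagnostics.items() if k != "accept"}
        diagnostics[slug] = diag
        if not ps.diagnostics.get("converged", True):
            unconverged.append(slug)
    (outdir / "diagnostics.json").write_text(
        json.dumps({"stamp": stamp, "groups": diagnostics, "unconverged": unconverged}, indent=2)
    )

    summaries = difference_summaries(fits, config.roles)
    report = baci.classify_baci(summaries, config.roles)
    report.metadata = {**stamp, "unconverged_groups": unconverged}
    for slug in unconverged:
        logger.warning("group %s failed the PSRF gate", slug)
    for row in report.rows:
        row_slug = f"{row['lake']}_{row['species']}".replace(" ", "-")
        row["unconverged"] = any(u.startswith(row_slug + "_") for u in unconverged)

    header = "\n".join(f"# {k}: {v}" for k, v in stamp.items())
    (outdir / "report.tsv").write_text(header + "\n" + baci.render_table(report, "tsv"))
    (outdir / "report.json").write_text(
        json.dumps(
            {
                "metadata": report.metadata,
                "rows": report.rows,
                "overlap_matrix": {
                    sp: {f"{a}|{b}": v for (a, b), v in mat.items()}
                    for sp, mat in report.overlap_matrix.items()
                },
            },
            indent=2,
            default=float,
        )
    )

    if unconverged and not config.allow_unconverged:
        raise ConvergenceError(
            f"{len(unconverged)} group fit(s) failed PSRF <= 1.05: {', '.join(unconverged)}"
        )
    return report
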