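"""End-to-end orchestration: ingest -> index -> regions -> reductions
-> change points, producing a bundle of CSV reports.

`run_pipeline` is the programmatic entry point behind `geomobility run`;
every stage is also callable on its own. All randomness (the simulator)
is seeded from the config, so identical configs produce identical
report files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from geomobility.changepoints import detect_changepoints
from geomobility.ingest import (
    AnalysisLevel,
    StreamStats,
    parse_event_stream,
    resolve_stream,
)
from geomobility.mobility import (
    aggregate_region_week,
    build_user_weeks,
    daily_moving_average,
    detect_data_loss_weeks,
)
from geomobility.reduction import PeriodSplit, build_reduction_report
from geomobility.regions import RegionSet, assign_users
from geomobility.simulate import SimConfig, simulate_checkins, write_stream

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one full pipeline pass."""

    outdir: Path
    events_path: Path | None = None          # JSONL input; None -> simulate
    sim: SimConfig | None = None             # used when events_path is None
    regions: RegionSet | None = None
    level: str = "national"
    city_name: str | None = None
    split: PeriodSplit = field(default_factory=PeriodSplit)
    min_tweets: int = 3
    dataloss_limit: float = 0.9975
    compute_daily: bool = True
    changepoint_min_segment: int = 7

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if self.min_tweets < 1:
            raise ValueError("min_tweets must be >= 1")


@dataclass
class RunResult:
    """In-memory handles to everything the pipeline wrote."""

    events: pd.DataFrame
    user_weeks: pd.DataFrame
    users: pd.DataFrame
    region_weekly: pd.DataFrame
    report: pd.DataFrame
    daily: pd.DataFrame | None
    changepoints: pd.DataFrame | None
    excluded_weeks: set
    counters: dict


def run_pipeline(config: RunConfig) -> RunResult:
    """Run every stage and write the report CSVs into ``config.outdir``."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    if config.events_path is None:
        sim = config.sim or SimConfig()
        logger.info("run: simulating %d users (seed %d)", sim.n_users, sim.seed)
        lines, truth = simulate_checkins(sim)
        events_path = outdir / "events.jsonl"
        write_stream(lines, events_path)
        truth.users.to_csv(outdir / "truth_users.csv", index=False)
        if config.regions is None:
            config.regions = sim.regions or None
    else:
        events_path = Path(config.events_path)

    stats = StreamStats()
    counters: dict = {}
    level = AnalysisLevel(level=config.level, city_name=config.city_name)
    resolved = list(resolve_stream(parse_event_stream(events_path, stats), level, counters))
    logger.info(
        "run/ingest: %d lines, %d resolved, %d excluded",
        stats.lines, counters.get("resolved", 0), counters.get("excluded", 0),
    )
    if not resolved:
        raise RuntimeError("ingest produced no resolved events")
    events = pd.DataFrame(
        [(e.user_id, e.timestamp, e.lat, e.lon) for e in resolved],
        columns=["user_id", "timestamp", "lat", "lon"],
    )

    probe = build_user_weeks(events, config.min_tweets, config.min_tweets)
    excluded = detect_data_loss_weeks(probe.weekly_totals, config.dataloss_limit)
    result = build_user_weeks(events, config.min_tweets, config.min_tweets, exclude_weeks=excluded)
    logger.info(
        "run/index: %d users, %d user-weeks, %d data-loss weeks excluded",
        len(result.users), len(result.user_weeks), len(excluded),
    )

    if config.regions is not None:
        assignment = assign_users(result.users, config.regions)
        logger.info("run/regions: %d/%d users assigned", len(assignment), len(result.users))
    else:
        assignment = {u: "all" for u in result.users["user_id"]}

    region_weekly = aggregate_region_week(result.user_weeks, assignment)
    report = build_reduction_report(events, result.user_weeks, assignment, config.split)

    result.user_weeks.to_csv(outdir / "user_weekly.csv", index=False)
    region_weekly.to_csv(outdir / "region_weekly.csv", index=False)
    report.to_csv(outdir / "reduction_report.csv", index=False)

    daily = None
    cps = None
    if config.compute_daily:
        daily = daily_moving_average(events, assignment=assignment)
        daily.to_csv(outdir / "daily_series.csv", index=False)
        rows = []
        for rid, g in daily.groupby("region_id"):
            s = g.sort_values("day").set_index("day")["index_km"]
            res = detect_changepoints(
                s, min_segment=config.changepoint_min_segment, series_id=str(rid)
            )
            for d in res.dates:
                rows.append((rid, d))
        cps = pd.DataFrame(rows, columns=["region_id", "change_date"])
        cps.to_csv(outdir / "changepoints.csv", index=False)
        logger.info("run/changepoints: %d points", len(cps))

    return RunResult(
        events=events,
        user_weeks=result.user_weeks,
        users=result.users,
        region_weekly=region_weekly,
        report=report,
        daily=daily,
        changepoints=cps,
        excluded_weeks=excluded,
        counters=counters,
    )
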