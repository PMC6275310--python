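"""End-to-end pipeline: files -> consensus -> metrics -> model -> report.

Stages mirror the analysis workflow: read rosters and SCM reports, drop
classroom-waves below the participation threshold, build each classroom's
consensus network by the intersection rule, score per-perceiver accuracy and
per-classroom transitivity, assemble the longitudinal table, and fit the
random-intercept model.  Every exclusion (low participation, empty true
network, undefined transitivity, too few waves) is logged with its reason.

Output tables are tab-separated with fixed column order and 4-decimal
formatting; rounding happens only at this presentation layer.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .consensus import (
    DEFAULT_PARTICIPATION_THRESHOLD,
    ClassroomWaveData,
    build_classroom_wave,
    filter_eligible,
    intersection_true_network,
)
from .io import FormatError, GroupReport, Roster, read_reports, read_roster, write_edge_list
from .longitudinal import ModelFit, assemble_long_table, fit_random_intercept
from .metrics import (
    AccuracyRecord,
    TransitivityRecord,
    score_classroom,
    score_perceiver,
)
from .network import AffiliativeNetwork
from .synthetic import SimulationConfig, simulate_study

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_simulation", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Either file inputs (roster + reports) or a simulation config — not both."""

    roster_path: Path | None = None
    reports_path: Path | None = None
    simulation: SimulationConfig | None = None
    participation_threshold: float = DEFAULT_PARTICIPATION_THRESHOLD
    min_waves: int = 2
    out_dir: Path = Path("scmnet_out")
    seed: int | None = None

    def __post_init__(self) -> None:
        has_files = self.roster_path is not None or self.reports_path is not None
        if has_files and self.simulation is not None:
            raise ValueError("set either input paths or a simulation config, not both")
        if not has_files and self.simulation is None:
            raise ValueError("one of input paths or a simulation config is required")
        if has_files and (self.roster_path is None or self.reports_path is None):
            raise ValueError("both roster_path and reports_path are required for file input")


@dataclass
class PipelineResult:
    true_networks: dict[tuple[str, int], AffiliativeNetwork]
    accuracy_records: list[AccuracyRecord]
    transitivity_records: list[TransitivityRecord]
    long_table: pd.DataFrame
    model_fit: ModelFit
    out_dir: Path
    excluded: list[str] = field(default_factory=list)


def _load_report_records(reports_path: Path, rosters: list[Roster]) -> dict[tuple[str, int], list[GroupReport]]:
    paths = sorted(reports_path.glob("*.json")) if reports_path.is_dir() else [reports_path]
    if not paths:
        raise FormatError(f"no report JSON files found under {reports_path}")
    by_wave: dict[tuple[str, int], list[GroupReport]] = {}
    for roster in rosters:
        collected: list[GroupReport] = []
        for path in paths:
            collected.extend(read_reports(path, roster))
        seen: dict[str, GroupReport] = {}
        for rep in collected:
            if rep.perceiver in seen:
                raise FormatError(
                    f"duplicate report for perceiver {rep.perceiver!r} in "
                    f"classroom {roster.classroom_id!r} wave {roster.wave_id}"
                )
            seen[rep.perceiver] = rep
        by_wave[(roster.classroom_id, roster.wave_id)] = list(seen.values())
    return by_wave


def _fmt(value: float) -> str:
    return "nan" if isinstance(value, float) and math.isnan(value) else f"{value:.4f}"


def _write_tables(result: PipelineResult, written: list[Path]) -> None:
    out = result.out_dir
    nets_dir = out / "true_networks"
    nets_dir.mkdir(parents=True, exist_ok=True)
    for (cid, wid), net in sorted(result.true_networks.items()):
        path = nets_dir / f"{cid}_w{wid}.tsv"
        write_edge_list(net, path)
        written.append(path)

    acc_path = out / "accuracy.tsv"
    with acc_path.open("w", encoding="utf-8") as fh:
        fh.write(
            "classroom_id\twave_id\tperceiver\tn_depicted\tn_correct\tn_true\t"
            "precision\tcoverage\taccuracy\n"
        )
        for r in sorted(result.accuracy_records, key=lambda r: (r.classroom_id, r.wave_id, r.perceiver)):
            fh.write(
                f"{r.classroom_id}\t{r.wave_id}\t{r.perceiver}\t{r.n_depicted}\t"
                f"{r.n_correct}\t{r.n_true}\t{_fmt(r.precision)}\t{_fmt(r.coverage)}\t"
                f"{_fmt(r.accuracy)}\n"
            )
    written.append(acc_path)

    trans_path = out / "transitivity.tsv"
    with trans_path.open("w", encoding="utf-8") as fh:
        fh.write("classroom_id\twave_id\tn_transitive_triads\tn_two_paths\ttransitivity\n")
        for t in sorted(result.transitivity_records, key=lambda t: (t.classroom_id, t.wave_id)):
            fh.write(
                f"{t.classroom_id}\t{t.wave_id}\t{t.n_transitive_triads}\t"
                f"{t.n_two_paths}\t{_fmt(t.transitivity)}\n"
            )
    written.append(trans_path)

    # per-wave descriptives (means/SDs), the descriptive-table layout
    summary_path = out / "wave_summary.tsv"
    acc = pd.DataFrame(
        [{"wave_id": r.wave_id, "accuracy": r.accuracy} for r in result.accuracy_records]
    )
    trans = pd.DataFrame(
        [
            {"wave_id": t.wave_id, "transitivity": t.transitivity}
            for t in result.transitivity_records
            if t.defined
        ]
    )
    with summary_path.open("w", encoding="utf-8") as fh:
        fh.write("wave_id\taccuracy_mean\taccuracy_sd\ttransitivity_mean\ttransitivity_sd\n")
        waves = sorted(
            set(acc["wave_id"].tolist() if not acc.empty else [])
            | set(trans["wave_id"].tolist() if not trans.empty else [])
        )
        for w in waves:
            a = acc.loc[acc["wave_id"] == w, "accuracy"] if not acc.empty else pd.Series(dtype=float)
            t = trans.loc[trans["wave_id"] == w, "transitivity"] if not trans.empty else pd.Series(dtype=float)
            fh.write(
                f"{w}\t{_fmt(a.mean())}\t{_fmt(a.std(ddof=1))}\t"
                f"{_fmt(t.mean())}\t{_fmt(t.std(ddof=1))}\n"
            )
    written.append(summary_path)

    model_path = out / "model_report.tsv"
    fit = result.model_fit
    with model_path.open("w", encoding="utf-8") as fh:
        fh.write("term\testimate\tse\tdf\tp_value\n")
        for fe in fit.fixed_effects:
            fh.write(
                f"{fe.name}\t{_fmt(fe.estimate)}\t{_fmt(fe.se)}\t{_fmt(fe.df)}\t{_fmt(fe.p_value)}\n"
            )
        fh.write(f"sigma2_intercept\t{_fmt(fit.sigma2_intercept)}\t\t\t\n")
        fh.write(f"sigma2_residual\t{_fmt(fit.sigma2_residual)}\t\t\t\n")
        fh.write(f"n_participants\t{fit.n_participants}\t\t\t\n")
        fh.write(f"n_observations\t{fit.n_observations}\t\t\t\n")
        fh.write(f"df_method\t{fit.df_method}\t\t\t\n")
    written.append(model_path)

    long_path = out / "long_table.tsv"
    result.long_table.to_csv(long_path, sep="\t", index=False, float_format="%.6f")
    written.append(long_path)


def analyze_classroom_waves(
    rosters: list[Roster],
    reports_by_wave: dict[tuple[str, int], list[GroupReport]],
    participation_threshold: float = DEFAULT_PARTICIPATION_THRESHOLD,
    min_waves: int = 2,
) -> tuple[
    dict[tuple[str, int], AffiliativeNetwork],
    list[AccuracyRecord],
    list[TransitivityRecord],
    pd.DataFrame,
    list[str],
]:
    """Consensus + metrics + long table for already-loaded data (no model fit)."""
    excluded: list[str] = []
    waves: list[ClassroomWaveData] = []
    for roster in rosters:
        reports = reports_by_wave.get((roster.classroom_id, roster.wave_id), [])
        waves.append(build_classroom_wave(roster, reports))

    eligible = filter_eligible(waves, participation_threshold)
    eligible_keys = {(cw.roster.classroom_id, cw.roster.wave_id) for cw in eligible}
    for cw in waves:
        key = (cw.roster.classroom_id, cw.roster.wave_id)
        if key not in eligible_keys:
            excluded.append(f"classroom {key[0]} wave {key[1]}: participation rate below threshold")

    true_networks: dict[tuple[str, int], AffiliativeNetwork] = {}
    accuracy_records: list[AccuracyRecord] = []
    transitivity_records: list[TransitivityRecord] = []
    for cw in eligible:
        cid, wid = cw.roster.classroom_id, cw.roster.wave_id
        missing = cw.roster.participants - set(cw.perceived)
        if missing:
            raise PipelineError(
                f"consensus stage: classroom {cid!r} wave {wid}: participants "
                f"without reports: {sorted(missing)}"
            )
        true = intersection_true_network(cw)
        true_networks[(cid, wid)] = true
        transitivity_records.append(score_classroom(cid, wid, true))
        if not true.edges:
            excluded.append(f"classroom {cid} wave {wid}: empty true network, accuracy undefined")
            logger.warning(
                "classroom %s wave %d: true network has no edges; skipping accuracy", cid, wid
            )
            continue
        for perceiver in sorted(cw.perceived):
            accuracy_records.append(
                score_perceiver(perceiver, cid, wid, cw.perceived[perceiver], true)
            )

    long_table = assemble_long_table(accuracy_records, transitivity_records, min_waves=min_waves)
    return true_networks, accuracy_records, transitivity_records, long_table, excluded


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write all output tables under ``config.out_dir``.

    On any stage failure, partially written outputs are removed and a
    PipelineError naming the stage is raised.
    """
    written: list[Path] = []
    try:
        if config.simulation is not None:
            sim = config.simulation
            if config.seed is not None:
                import dataclasses as _dc

                sim = _dc.replace(sim, seed=config.seed)
            study = simulate_study(sim)
            rosters = list(study.rosters)
            reports_by_wave = {k: list(v) for k, v in study.reports.items()}
        else:
            try:
                rosters = read_roster(config.roster_path)
            except FileNotFoundError as exc:
                raise PipelineError(f"input stage: roster not found: {config.roster_path}") from exc
            if not rosters:
                raise PipelineError(f"input stage: roster file {config.roster_path} is empty")
            try:
                reports_by_wave = _load_report_records(Path(config.reports_path), rosters)
            except FileNotFoundError as exc:
                raise PipelineError(
                    f"input stage: reports not found: {config.reports_path}"
                ) from exc

        true_networks, accuracy_records, transitivity_records, long_table, excluded = (
            analyze_classroom_waves(
                rosters,
                reports_by_wave,
                participation_threshold=config.participation_threshold,
                min_waves=config.min_waves,
            )
        )
        if long_table.empty:
            raise PipelineError("model stage: no participant-waves left after exclusions")
        try:
            fit = fit_random_intercept(long_table)
        except Exception as exc:
            raise PipelineError(f"model stage: {exc}") from exc

        result = PipelineResult(
            true_networks=true_networks,
            accuracy_records=accuracy_records,
            transitivity_records=transitivity_records,
            long_table=long_table,
            model_fit=fit,
            out_dir=Path(config.out_dir),
            excluded=excluded,
        )
        result.out_dir.mkdir(parents=True, exist_ok=True)
        _write_tables(result, written)
        exclusions_path = result.out_dir / "exclusions.log"
        exclusions_path.write_text(
            "".join(line + "\n" for line in excluded), encoding="utf-8"
        )
        written.append(exclusions_path)
        return result
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def run_simulation(config: PipelineConfig) -> Path:
    """Materialise a synthetic study (dataset files + truth record) on disk."""
    if config.simulation is None:
        raise ValueError("run_simulation requires a simulation config")
    sim = config.simulation
    if config.seed is not None:
        import dataclasses as _dc

        sim = _dc.replace(sim, seed=config.seed)
    if sim.n_waves < config.min_waves:
        raise ValueError(
            f"n_waves={sim.n_waves} cannot satisfy the longitudinal inclusion rule "
            f"(min_waves={config.min_waves})"
        )
    out = Path(config.out_dir)
    simulate_study(sim, out_dir=out)
    return out


def recovery_report(study_dir: Path, result: PipelineResult) -> dict:
    """Compare a pipeline run against the planted truth record of a simulation."""
    truth = json.loads((study_dir / "truth" / "truth.json").read_text(encoding="utf-8"))
    planted_t = truth["planted_transitivity"]
    rows = []
    for rec in result.transitivity_records:
        key = f"{rec.classroom_id}:{rec.wave_id}"
        if key in planted_t and rec.defined:
            rows.append((planted_t[key], rec.transitivity))
    corr = float("nan")
    if len(rows) >= 2:
        s = pd.DataFrame(rows, columns=["planted", "recovered"])
        corr = float(s["planted"].corr(s["recovered"]))
    b2 = result.model_fit.coefficient("transitivity_t0")
    b3 = result.model_fit.coefficient("transitivity_change")
    return {
        "n_classroom_waves_compared": len(rows),
        "transitivity_correlation": corr,
        "beta_transitivity_t0": b2.estimate,
        "beta_transitivity_t0_p": b2.p_value,
        "beta_transitivity_change": b3.estimate,
        "beta_transitivity_change_p": b3.p_value,
    }
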