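"""Readers, writers, orchestration and provenance for the analysis pipeline.

CSV is the interchange format for data tables and JSON for configuration and
model output.  A run manifest records digests, row counts, seeds and stage
durations so deterministic stages can be verified bit-for-bit on re-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .psychometric import BlockData, PriorConfig, fit_block
from .prior_selection import DEFAULT_WIDTHS, loo_cv, select_prior_width
from .reading_analysis import ModelSpec, stepwise_simplify
from .rt_analysis import filter_rts, rt_mixed_model, rt_mode_table
from .shape_metrics import aggregate_blocks, attach_pc1, filter_valid_fits, shape_records
from .simulate import SimConfig, simulate_cohort

log = logging.getLogger("lapsefit")

TRIAL_COLUMNS = {
    "subject_id": str, "continuum": str, "paradigm": str, "block_index": int,
    "trial_number": int, "step": int, "response": int, "rt_ms": float,
}
SUBJECT_COLUMNS = {
    "subject_id": str, "wj_brs": float, "group": str, "age": float,
    "adhd": int, "nonverbal_iq": float,
}


class SchemaError(ValueError):
    """Input file does not match the documented schema."""


def _validate(frame: pd.DataFrame, schema: dict, name: str) -> pd.DataFrame:
    missing = set(schema) - set(frame.columns)
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {sorted(missing)}")
    return frame.astype(schema)


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-level CSV (one row per trial).

    Steps must be integers 1–7 and responses binary; violations are reported
    with their (0-based) row numbers.  An empty file with a valid header
    returns an empty table with a warning.
    """
    frame = pd.read_csv(path)
    frame = _validate(frame, TRIAL_COLUMNS, Path(path).name)
    if len(frame) == 0:
        log.warning("%s: no trial rows", path)
        return frame
    bad_step = ~frame["step"].isin(range(1, 8))
    if bad_step.any():
        rows = frame.index[bad_step].tolist()[:10]
        raise SchemaError(f"step outside 1..7 at row(s) {rows}")
    bad_resp = ~frame["response"].isin((0, 1))
    if bad_resp.any():
        rows = frame.index[bad_resp].tolist()[:10]
        raise SchemaError(f"non-binary response at row(s) {rows}")
    return frame


def read_subjects_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-subject covariate CSV."""
    return _validate(pd.read_csv(path), SUBJECT_COLUMNS, Path(path).name)


def blocks_from_trials(trials: pd.DataFrame) -> list[BlockData]:
    """Group a validated trial table into per-block data objects."""
    out = []
    for (sid, bidx), grp in trials.groupby(["subject_id", "block_index"], sort=True):
        out.append(
            BlockData.from_trials(
                grp[["trial_number", "step", "response", "rt_ms"]],
                subject_id=sid,
                continuum=grp["continuum"].iloc[0],
                paradigm=grp["paradigm"].iloc[0],
                block_index=int(bidx),
            )
        )
    return out


def fits_to_frame(blocks: list[BlockData], fits, prior: PriorConfig) -> pd.DataFrame:
    """One output row per fitted block (probabilities at 6-digit precision)."""
    rows = []
    for b, f in zip(blocks, fits):
        pe = f.point_estimate
        rows.append(
            {
                "subject_id": b.subject_id, "continuum": b.continuum,
                "paradigm": b.paradigm, "block_index": b.block_index,
                "prior_asym_max": prior.asym_max,
                "threshold": round(pe.threshold, 6), "width": round(pe.width, 6),
                "slope": round(f.slope_at_threshold, 6),
                "lower_asym": round(pe.lower_asym, 6),
                "upper_asym_dev": round(pe.upper_asym_dev, 6),
                "log_evidence": round(f.log_evidence, 6),
                "excluded": f.excluded, "exclusion_reason": f.exclusion_reason or "",
            }
        )
    return pd.DataFrame(rows)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    seed: int
    package_version: str = __version__
    config: dict = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    files: dict[str, str] = field(default_factory=dict)

    def add_stage(self, name: str, seconds: float, **counts) -> None:
        self.stages.append({"stage": name, "seconds": round(seconds, 3), **counts})

    def add_file(self, path: Path) -> None:
        self.files[path.name] = _digest(path)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def _prepare_model_table(cells: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    tab = cells.merge(subjects, on="subject_id")
    tab["continuum_dev"] = np.where(tab["continuum"] == "static_sha_sa", 0.5, -0.5)
    tab["paradigm_dev"] = np.where(tab["paradigm"] == "abx", 0.5, -0.5)
    tab["wj_brs_c"] = tab["wj_brs"] - tab["wj_brs"].mean()
    return tab


FULL_SHAPE_TERMS = ["wj_brs_c", "continuum_dev", "paradigm_dev", "adhd", "nonverbal_iq"]


def run_pipeline(
    out_dir: str | Path,
    trials: pd.DataFrame | None = None,
    subjects: pd.DataFrame | None = None,
    sim_config: SimConfig | None = None,
    prior: PriorConfig | None = None,
    run_cv: bool = False,
    cv_widths=DEFAULT_WIDTHS,
    seed: int = 0,
) -> RunManifest:
    """Execute fit → (optional CV) → shapes → models → RT stages in order.

    Either pass trial/subject tables or a ``sim_config`` to generate a
    synthetic cohort.  Every intermediate table is written as CSV/JSON under
    ``out_dir`` together with a manifest of digests, row counts and stage
    durations.  Any stage failure propagates with the completed stages
    recorded in the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed)
    prior = prior or PriorConfig()

    if trials is None:
        cfg = sim_config or SimConfig(seed=seed)
        manifest.config = asdict(cfg)
        t0 = time.time()
        cohort = simulate_cohort(cfg)
        trials, subjects = cohort.trials, cohort.subjects
        paths = cohort.to_csv(out)
        for p in paths.values():
            manifest.add_file(p)
        manifest.add_stage("simulate", time.time() - t0, n_subjects=len(subjects),
                           n_trials=len(trials))
    if subjects is None:
        raise ValueError("subject covariates are required when passing real trials")

    blocks = blocks_from_trials(trials)

    if run_cv:
        t0 = time.time()
        cv = loo_cv(blocks, tuple(cv_widths), base_prior=prior)
        width = select_prior_width(cv)
        p = out / "cv_prior.csv"
        cv.medians.to_csv(p, index=False, float_format="%.6f")
        manifest.add_file(p)
        manifest.add_stage("cv_prior", time.time() - t0, selected_width=width)
        prior = PriorConfig(
            asym_max=width, threshold_range=prior.threshold_range,
            width_range=prior.width_range, grid_points=prior.grid_points,
            grid_points_asym=prior.grid_points_asym,
        )

    t0 = time.time()
    fits = [fit_block(b, prior) for b in blocks]
    kept, excluded = filter_valid_fits(fits)
    # rebuild a list aligned with blocks, using the flagged copies for exclusions
    by_id = {id(e.point_estimate): e for e in excluded}
    aligned = [by_id.get(id(f.point_estimate), f) for f in fits]
    fit_frame = fits_to_frame(blocks, aligned, prior)
    p = out / "fits.csv"
    fit_frame.to_csv(p, index=False, float_format="%.6f")
    manifest.add_file(p)
    manifest.add_stage("fit", time.time() - t0, n_blocks=len(blocks), n_excluded=len(excluded))

    t0 = time.time()
    records = shape_records(blocks, aligned)
    cells, grand = aggregate_blocks(records)
    cells, pca = attach_pc1(cells)
    p = out / "shapes.csv"
    cells.to_csv(p, index=False, float_format="%.6f")
    manifest.add_file(p)
    manifest.add_stage("shapes", time.time() - t0, n_cells=len(cells),
                       pc1_variance=round(pca.variance_fraction, 4))

    t0 = time.time()
    table = _prepare_model_table(cells, subjects)
    # covariates without variation (e.g. no ADHD cases in a small cohort)
    # cannot enter the design
    terms = [t for t in FULL_SHAPE_TERMS if table[t].nunique() > 1]
    models = {}
    for response in ("slope", "lapse", "pc1"):
        final = stepwise_simplify(table, ModelSpec(response, list(terms)))
        models[response] = {
            "terms": final.terms.to_dict("records"),
            "trace": final.trace,
            "loglik": final.loglik,
        }
    p = out / "models.json"
    p.write_text(json.dumps(models, indent=2))
    manifest.add_file(p)
    manifest.add_stage("models", time.time() - t0)

    t0 = time.time()
    kept_rt, rem_lo, rem_hi, fractions = filter_rts(trials)
    rt_model = rt_mixed_model(kept_rt, subjects)
    modes = rt_mode_table(kept_rt)
    p = out / "rt_modes.csv"
    modes.to_csv(p, index=False, float_format="%.6f")
    manifest.add_file(p)
    p = out / "rt_model.json"
    p.write_text(json.dumps({"terms": rt_model.terms.to_dict("records"),
                             "filter_fractions": fractions}, indent=2))
    manifest.add_file(p)
    manifest.add_stage("rt", time.time() - t0, n_kept=len(kept_rt),
                       n_removed_low=len(rem_lo), n_removed_high=len(rem_hi))

    manifest.write(out / "manifest.json")
    return manifest


def write_report(artifacts_dir: str | Path) -> Path:
    """Render a plain-markdown summary of a completed run's artifacts."""
    art = Path(artifacts_dir)
    lines = ["# Pipeline report", ""]
    manifest = json.loads((art / "manifest.json").read_text())
    lines.append(f"Package version {manifest['package_version']}, seed {manifest['seed']}.")
    lines.append("")
    lines.append("## Stages")
    for st in manifest["stages"]:
        extras = {k: v for k, v in st.items() if k not in ("stage", "seconds")}
        lines.append(f"- **{st['stage']}** ({st['seconds']}s) {extras}")
    excl = next((s.get("n_excluded") for s in manifest["stages"] if s["stage"] == "fit"), None)
    if excl is not None:
        lines += ["", f"Blocks excluded by the threshold-range rule: {excl}"]
    cv_path = art / "cv_prior.csv"
    if cv_path.exists():
        lines += ["", "## Median held-out likelihood by prior width", ""]
        cv = pd.read_csv(cv_path)
        lines.append(cv.to_markdown(index=False))
    models_path = art / "models.json"
    if models_path.exists():
        models = json.loads(models_path.read_text())
        lines += ["", "## Parsimonious mixed models"]
        for name, m in models.items():
            lines.append(f"### {name}")
            terms = pd.DataFrame(m["terms"])
            lines.append(terms.to_markdown(index=False))
            if m["trace"]:
                dropped = ", ".join(t["dropped"] for t in m["trace"])
                lines.append(f"Dropped terms (in order): {dropped}")
    report = art / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
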