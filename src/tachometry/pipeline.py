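"""End-to-end analysis: exclusions -> curves -> minima -> inference -> tables.

``run_pipeline`` executes the whole chain on either a trial-log CSV or a
freshly simulated experiment, writes every intermediate as CSV/JSON into
the output directory, and records a machine-readable run manifest with all
seeds. Given fixed seeds the bundle is byte-reproducible. Any stage error
aborts the run and removes partial outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

from . import __version__
from .anova import (
    bin_accuracy_100ms,
    congruency_effect,
    format_posthoc_table,
    posthoc_paired_t,
    rm_anova_2way,
)
from .behavior import simulate_experiment
from .config import PipelineConfig
from .curves import (
    bootstrap_minimum_se,
    curve_minimum,
    curves_to_frame,
    minima_to_json,
    tachometric_curves,
)
from .design import generate_design
from .permutation import permutation_test_minima
from .trials import CONGRUENCIES, apply_exclusions, read_trial_table, write_trial_table

log = logging.getLogger("tachometry")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a dict of result objects and paths."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def track(path: Path) -> Path:
        written.append(path)
        return path

    results: dict = {}
    stage = "setup"
    try:
        stage = "input"
        if config.simulate:
            log.info("simulating %s: %d participant(s), design seed %d, "
                     "response seed %d", config.task, config.n_participants,
                     config.design_seed, config.response_seed)
            design = generate_design(config.design_spec())
            table = simulate_experiment(design, config.model,
                                        seed=config.response_seed)
            write_trial_table(table, track(out_dir / "trials.csv"))
        else:
            table = read_trial_table(config.input_path)
        results["n_trials_input"] = len(table)

        stage = "exclusions"
        analyzed, report = apply_exclusions(
            table, rpt_lo=config.rpt_lo, rpt_hi=config.rpt_hi,
            drop_late=config.drop_late,
        )
        log.info("exclusions: %s", report)
        results["filter_report"] = report

        stage = "tachometric"
        curves = tachometric_curves(
            analyzed, span=config.span, degree=config.degree,
            bin_width=config.pool_bin_width,
        )
        curves_to_frame(curves).to_csv(track(out_dir / "curves.csv"), index=False)
        minima = {c: curve_minimum(curves[c], config.rpt_lo, config.rpt_hi)
                  for c in curves}
        results["curves"] = curves
        results["minima"] = minima

        stage = "bootstrap"
        ses = {
            c: bootstrap_minimum_se(
                analyzed, c, n_reps=config.bootstrap_reps,
                seed=config.bootstrap_seed + i, span=config.span,
                degree=config.degree, bin_width=config.pool_bin_width,
                search_lo=config.rpt_lo, search_hi=config.rpt_hi,
            )
            for i, c in enumerate(CONGRUENCIES)
        }
        minima_to_json(minima, ses, track(out_dir / "minima.json"))
        results["bootstrap"] = ses

        stage = "permutation"
        perm = permutation_test_minima(
            analyzed, B=config.permutation_B, seed=config.permutation_seed,
            span=config.span, degree=config.degree,
            sidedness=config.sidedness, bin_width=config.pool_bin_width,
            search_lo=config.rpt_lo, search_hi=config.rpt_hi,
        )
        perm.to_json(track(out_dir / "permutation.json"))
        results["permutation"] = perm
        log.info("permutation: diff=%.4f p=%.4g d_z=%.2f",
                 perm.observed_diff, perm.p_value, perm.d_z)

        stage = "binned"
        bt = bin_accuracy_100ms(analyzed, lo=config.bin_lo, hi=config.bin_hi,
                                bin_width=config.bin_width)
        anova = rm_anova_2way(bt)
        anova.to_frame().to_csv(track(out_dir / "anova.csv"), index=False)
        pooled = (bt.condition_matrix("congruent")
                  + bt.condition_matrix("incongruent")) / 2
        posthoc_bins = posthoc_paired_t(pooled)
        format_posthoc_table(posthoc_bins).to_csv(
            track(out_dir / "posthoc_bins.csv"), index=False)
        effect = congruency_effect(bt)
        effect.to_csv(track(out_dir / "congruency_effect.csv"))
        posthoc_eff = posthoc_paired_t(effect)
        format_posthoc_table(posthoc_eff).to_csv(
            track(out_dir / "posthoc_congruency_effect.csv"), index=False)
        results.update(binned=bt, anova=anova, posthoc_bins=posthoc_bins,
                       congruency_effect=effect, posthoc_effect=posthoc_eff)

        stage = "figures"
        if config.make_figures:
            from .plotting import plot_congruency_effect, plot_curves

            for p in plot_curves(curves, minima, ses,
                                 out=out_dir / "tachometric"):
                track(p)
            for p in plot_congruency_effect(effect,
                                            out=out_dir / "congruency_effect"):
                track(p)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": _config_dict(config),
            "filter_report": asdict(report),
            "minima": minima_to_json(minima, ses),
            "permutation": perm.to_json(),
            "outputs": [str(p) for p in written],
        }
        (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
        results["manifest_path"] = out_dir / "run_manifest.json"
    except Exception as exc:
        for p in written:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    return results


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["model"]["rt_bounds"] = list(config.model.rt_bounds)
    return d
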