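"""End-to-end workflows: simulate -> quantify -> test, as one report.

Two workflows mirror the study's two quantitative arms:

* ``migration`` — generate cohorts from named presets, measure distances,
  summarise, and classify each test condition with the rescue rule against
  the control and phenotype cohorts;
* ``association`` — generate a planted genome/peak set and expression
  matrix, select deregulated genes, and test binding enrichment of the
  up- and down-regulated sets against the resampling null.

The JSON report records every statistic together with the seed, package
version, thresholds and a hash of the configuration, so runs are fully
reproducible and auditable.
"""

from __future__ import annotations

import dataclasses

import gzexit
from gzexit import io
from gzexit.expression import select_deregulated
from gzexit.migration import (
    RESCUE_CHI2_P,
    RESCUE_T_P,
    classify_rescue,
    distance_to_surface,
    summarize_cohort,
)
from gzexit.peakgene import assign_peaks_to_genes, resample_association
from gzexit.presets import COHORT_PRESETS
from gzexit.synthetic import (
    ExpressionSimConfig,
    PlantedAssociationConfig,
    generate_cohort,
    generate_expression,
    generate_genome_and_peaks,
)


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - re-tag for the report
                raise PipelineError(f"[{name}] {e}") from e
        return wrapped
    return deco


@_stage("migration")
def _run_migration(config: dict, seed: int) -> dict:
    bin_width = float(config.get("bin_width_um", 10.0))
    thresholds = config.get(
        "thresholds", {"chi2_p": RESCUE_CHI2_P, "t_p": RESCUE_T_P}
    )

    def profile(preset_name: str):
        cohort = generate_cohort(COHORT_PRESETS[preset_name], seed)
        d = distance_to_surface(cohort)
        return summarize_cohort(d, bin_width_um=bin_width, condition=preset_name)

    control = profile(config["control"])
    phenotype = profile(config["phenotype"])
    profiles = {config["control"]: control, config["phenotype"]: phenotype}
    verdicts = {}
    for name in config.get("tests", []):
        prof = profile(name)
        profiles[name] = prof
        v = classify_rescue(
            control, phenotype, prof,
            chi2_p_threshold=float(thresholds["chi2_p"]),
            t_p_threshold=float(thresholds["t_p"]),
        )
        verdicts[name] = dataclasses.asdict(v)
    return {
        "profiles": {
            k: {f: p.to_dict()[f]
                for f in ("condition", "mean_um", "sd_um", "n", "p99_um")}
            for k, p in profiles.items()
        },
        "verdicts": verdicts,
        "bin_width_um": bin_width,
        "thresholds": thresholds,
    }


@_stage("association")
def _run_association(config: dict, seed: int) -> dict:
    planted = PlantedAssociationConfig(**{**config.get("planted", {}), "seed": seed})
    expr_cfg = ExpressionSimConfig(**{**config.get("expression", {}), "seed": seed})
    n_resample = int(config.get("n_resample", 1000))

    if planted.n_genes != expr_cfg.n_genes:
        raise ValueError("planted and expression configs must share n_genes")
    matrix = generate_expression(expr_cfg)
    # the bound block is the repressed expression block, so binding is
    # genuinely associated with down-regulation in the simulated data
    block = set(matrix.values.index[: expr_cfg.repressed_block_size])
    genes, peaks, target_ids = generate_genome_and_peaks(planted, target_ids=block)
    assignments = assign_peaks_to_genes(peaks, genes)
    perturbed = expr_cfg.perturbed_condition or expr_cfg.conditions[-1]
    baseline = next(c for c in expr_cfg.conditions if c != perturbed)
    de = select_deregulated(matrix, perturbed, baseline)

    universe = genes["gene_id"]
    out = {"n_peaks": int(len(peaks)), "n_target_genes": len(target_ids)}
    for direction in ("down", "up"):
        gene_set = set(de.index[de["selected"] & (de["direction"] == direction)])
        if not gene_set:
            out[direction] = {"n_genes": 0}
            continue
        res = resample_association(
            assignments, gene_set, universe, n_resample=n_resample, seed=seed
        )
        out[direction] = {"n_genes": len(gene_set), **dataclasses.asdict(res)}
    return out


def run_pipeline(config: dict, seed: int | None = None) -> dict:
    """Execute the configured workflow and return the report bundle.

    ``config['workflow']`` selects ``migration`` or ``association``; the
    remaining keys parameterize that workflow.  ``seed`` overrides
    ``config['seed']`` when given.
    """
    seed = int(config.get("seed", 0) if seed is None else seed)
    workflow = config.get("workflow")
    runners = {"migration": _run_migration, "association": _run_association}
    if workflow not in runners:
        raise PipelineError(
            f"[config] unknown workflow {workflow!r}; expected one of "
            f"{sorted(runners)}"
        )
    results = runners[workflow](config, seed)
    return {
        "package": "gzexit",
        "version": gzexit.__version__,
        "workflow": workflow,
        "seed": seed,
        "config_sha256": io.config_hash(config),
        "results": results,
    }
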