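"""Command-line entry points and end-to-end workflows.

Thin wrappers over the library: simulate a population, fit single-cell
GLMs or the population tensor model, select the stimulus rank, sample the
posterior, summarize subspace geometry, and run the decoding analyses.
Every stochastic stage takes an explicit seed; ``run_workflow`` writes a
manifest recording the configuration and all seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import click
import numpy as np

from . import core_data
from .bases import BasisSet
from .synthetic import TaskSchedule, sample_ground_truth, simulate_trials
from .task_design import DesignSpec

logger = logging.getLogger(__name__)


def run_workflow(config: dict, out_dir: str) -> Path:
    """simulate -> fit -> rank-select -> geometry on one synthetic population.

    ``config`` keys (all optional): template, N, rank, trials_per_direction,
    seed, ranks (list for selection), folds, compact (bool).
    Writes data/, fits/, reports/ under ``out_dir`` plus a manifest.
    """
    from .model_selection import rank_selection_study

    out = Path(out_dir)
    for sub in ("data", "fits", "reports"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    cfg = {
        "template": "mixed",
        "N": 8,
        "rank": 2,
        "trials_per_direction": 20,
        "seed": 0,
        "ranks": [1, 2, 3],
        "folds": 3,
        "compact": True,
    }
    cfg.update(config)
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
    }
    sched = TaskSchedule().compact() if cfg["compact"] else TaskSchedule()
    truth = sample_ground_truth(
        cfg["template"], cfg["N"], cfg["rank"], seed=cfg["seed"], schedule=sched
    )
    data = simulate_trials(truth, cfg["trials_per_direction"], seed=cfg["seed"] + 1)
    core_data.save_hdf5(data, str(out / "data" / "population.h5"))
    spec = truth.model.spec
    study = rank_selection_study(
        data,
        spec,
        truth.model.bases,
        ranks=cfg["ranks"],
        K=cfg["folds"],
        seed=cfg["seed"] + 2,
        include_history=False,
        include_tbar=sched.touchbar_policy != "none",
    )
    report = {
        "frac": {str(r): v for r, v in study["frac"].items()},
        "selected_rank": study["selected_rank"],
        "threshold_reached": study["threshold_reached"],
    }
    (out / "reports" / "rank_selection.json").write_text(json.dumps(report, indent=2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


@click.group()
@click.option("-v", "--verbose", is_flag=True)
def cli(verbose: bool):
    """Low-rank tensor point-process models for neural populations."""
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


@cli.command()
@click.option("--template", default="mixed", type=click.Choice(["categoryless", "category_axis", "circular_direction", "mixed"]))
@click.option("--n-neurons", "-N", default=10)
@click.option("--rank", default=2)
@click.option("--trials-per-direction", default=20)
@click.option("--seed", default=0)
@click.option("--compact", is_flag=True, help="short trials (fast fitting studies)")
@click.option("--out", required=True, type=click.Path())
def simulate(template, n_neurons, rank, trials_per_direction, seed, compact, out):
    """Simulate a population from a ground-truth tensor model."""
    sched = TaskSchedule().compact() if compact else TaskSchedule()
    truth = sample_ground_truth(template, n_neurons, rank, seed=seed, schedule=sched)
    data = simulate_trials(truth, trials_per_direction, seed=seed + 1)
    core_data.save_hdf5(data, out)
    click.echo(f"wrote {len(data.trials)} trials / {data.n_neurons} neurons to {out}")


@cli.command("fit-glm")
@click.option("--data", "data_path", required=True, type=click.Path(exists=True))
@click.option("--parameterization", default="cosine")
@click.option("--neuron", default=None, help="fit a single neuron id")
@click.option("--evidence/--no-evidence", default=False)
@click.option("--out", required=True, type=click.Path())
def fit_glm_cmd(data_path, parameterization, neuron, evidence, out):
    """Fit single-cell GLMs (MAP, optionally with evidence optimization)."""
    from . import glm as glm_mod

    data = core_data.load_hdf5(data_path)
    spec = DesignSpec(parameterization=parameterization, direction_set_deg=tuple(data.direction_set_deg))
    bases = BasisSet.default(bin_width=data.bin_width)
    results = {}
    ids = [neuron] if neuron else data.neuron_ids
    for nid in ids:
        trials = data.trials_of(nid)
        design = glm_mod.build_design(trials, spec, bases, data.bin_width)
        if evidence:
            params, hyper = glm_mod.optimize_evidence(design, spec)
        else:
            hyper = glm_mod.default_hyper(spec)
            params = glm_mod.fit_map(design, glm_mod.build_prior(spec, hyper, design))
        results[nid] = {
            "w": params.w,
            "h_coeffs": params.h_coeffs.tolist(),
            "tbar_coeffs": params.tbar_coeffs.tolist(),
            "stim_coeffs": params.stim_coeffs.tolist(),
            "hyper": hyper,
        }
    Path(out).write_text(json.dumps(results, indent=2))
    click.echo(f"fit {len(results)} neurons -> {out}")


@cli.command("fit-gmlm")
@click.option("--data", "data_path", required=True, type=click.Path(exists=True))
@click.option("--parameterization", default="cosine")
@click.option("--rank", default=2)
@click.option("--no-history", is_flag=True)
@click.option("--no-tbar", is_flag=True)
@click.option("--seed", default=0)
@click.option("--out", required=True, type=click.Path())
def fit_gmlm_cmd(data_path, parameterization, rank, no_history, no_tbar, seed, out):
    """Maximum-likelihood fit of the population tensor model."""
    import h5py

    from .gmlm import GmlmModel

    data = core_data.load_hdf5(data_path)
    spec = DesignSpec(parameterization=parameterization, direction_set_deg=tuple(data.direction_set_deg))
    bases = BasisSet.default(bin_width=data.bin_width)
    model = GmlmModel(
        spec, bases, data.n_neurons, rank,
        include_history=not no_history, include_tbar=not no_tbar,
        bin_width=data.bin_width,
    )
    design = model.build_design(data)
    params = model.fit_mle(design, rng=np.random.default_rng(seed))
    with h5py.File(out, "w") as f:
        f.attrs["rank"] = rank
        f.attrs["parameterization"] = parameterization
        for name in ("w", "T_stim", "U_stim", "V_stim"):
            f.create_dataset(name, data=getattr(params, name))
        if params.H_spk is not None:
            f.create_dataset("H_spk", data=params.H_spk)
        if params.T_tbar is not None:
            f.create_dataset("T_tbar", data=params.T_tbar)
            f.create_dataset("V_tbar", data=params.V_tbar)
    click.echo(f"log-likelihood {model.log_likelihood(params, design):.1f} -> {out}")


@cli.command("rank-select")
@click.option("--data", "data_path", required=True, type=click.Path(exists=True))
@click.option("--parameterization", default="cosine")
@click.option("--ranks", default="1,2,3,4")
@click.option("--folds", default=10)
@click.option("--seed", default=0)
@click.option("--no-history", is_flag=True)
@click.option("--no-tbar", is_flag=True)
@click.option("--out", required=True, type=click.Path())
def rank_select_cmd(data_path, parameterization, ranks, folds, seed, no_history, no_tbar, out):
    """Cross-validated stimulus-rank selection (TSV report)."""
    from .model_selection import rank_selection_study

    data = core_data.load_hdf5(data_path)
    spec = DesignSpec(parameterization=parameterization, direction_set_deg=tuple(data.direction_set_deg))
    bases = BasisSet.default(bin_width=data.bin_width)
    study = rank_selection_study(
        data, spec, bases,
        ranks=[int(r) for r in ranks.split(",")],
        K=folds, seed=seed,
        include_history=not no_history, include_tbar=not no_tbar,
    )
    lines = ["rank\tdelta_lp\tfrac"]
    for r, rep in study["reports"].items():
        lines.append(
            f"{r}\t{rep.delta(study['report_rank0']):.4f}\t{study['frac'][r]:.4f}"
        )
    lines.append(f"# selected_rank={study['selected_rank']}")
    Path(out).write_text("\n".join(lines) + "\n")
    click.echo(f"selected rank {study['selected_rank']} -> {out}")


@cli.command()
@click.option("--data", "data_path", required=True, type=click.Path(exists=True))
@click.option("--parameterization", default="cosine")
@click.option("--rank", default=2)
@click.option("--warmup", default=2500)
@click.option("--samples", default=5000)
@click.option("--seed", default=0)
@click.option("--no-history", is_flag=True)
@click.option("--no-tbar", is_flag=True)
@click.option("--out", required=True, type=click.Path())
def sample(data_path, parameterization, rank, warmup, samples, seed, no_history, no_tbar, out):
    """HMC posterior sampling; writes draws (HDF5) and diagnostics (JSON)."""
    import h5py

    from .gmlm import GmlmModel
    from .inference import SamplerConfig, run_sampler

    data = core_data.load_hdf5(data_path)
    spec = DesignSpec(parameterization=parameterization, direction_set_deg=tuple(data.direction_set_deg))
    bases = BasisSet.default(bin_width=data.bin_width)
    model = GmlmModel(
        spec, bases, data.n_neurons, rank,
        include_history=not no_history, include_tbar=not no_tbar,
        bin_width=data.bin_width,
    )
    design = model.build_design(data)
    cfg = SamplerConfig.scaled(warmup, samples, seed=seed)
    post = run_sampler(model, design, cfg)
    with h5py.File(out, "w") as f:
        f.create_dataset("param_draws", data=post.param_draws)
        f.create_dataset("hyper_draws", data=post.hyper_draws)
        f.attrs["hyper_names"] = post.hyper_names
        f.attrs["acceptance_rate"] = post.acceptance_rate
    diag = {
        "acceptance_rate": post.acceptance_rate,
        "n_divergent": post.n_divergent,
        "eps_final": float(post.eps_trace[-1]),
    }
    Path(str(out) + ".diag.json").write_text(json.dumps(diag, indent=2))
    click.echo(f"acceptance {post.acceptance_rate:.3f} -> {out}")


@cli.command()
@click.option("--data", "data_path", required=True, type=click.Path(exists=True))
@click.option("--window-ms", default=200)
@click.option("--n-boot", default=1000)
@click.option("--n-times", default=8)
@click.option("--seed", default=0)
@click.option("--out", required=True, type=click.Path())
def decode(data_path, window_ms, n_boot, n_times, seed, out):
    """Direction-split category-generalization timecourse (TSV)."""
    from .decoding import benjamini_hochberg, category_generalization_timecourse

    data = core_data.load_hdf5(data_path)
    wb = int(round(window_ms / 1000.0 / data.bin_width))
    Tmin = min(t.n_bins for t in data.trials)
    centers = np.linspace(wb // 2, Tmin - wb // 2 - 1, n_times).astype(int)
    res = category_generalization_timecourse(
        data, centers, window_bins=wb, n_boot=n_boot, seed=seed,
        boundary=data.boundary_deg,
    )
    sig = benjamini_hochberg(res["p_value"])
    lines = ["time_ms\tmedian\tlo99\thi99\tsignificant"]
    for i, c in enumerate(res["times_bins"]):
        lines.append(
            f"{c * data.bin_width * 1000:.0f}\t{res['median'][i]:.4f}"
            f"\t{res['lo99'][i]:.4f}\t{res['hi99'][i]:.4f}\t{int(sig[i])}"
        )
    Path(out).write_text("\n".join(lines) + "\n")
    click.echo(f"decoding timecourse -> {out}")


@cli.command("single-neuron")
@click.option("--data", "data_path", required=True, type=click.Path(exists=True))
@click.option("--window", default="sample", type=click.Choice(["sample", "delay"]))
@click.option("--out", required=True, type=click.Path())
def single_neuron(data_path, window, out):
    """Per-neuron rCTI / rDSI table (TSV)."""
    from .classical_metrics import DELAY_WINDOW, SAMPLE_WINDOW, rcti, rdsi

    data = core_data.load_hdf5(data_path)
    w = SAMPLE_WINDOW if window == "sample" else DELAY_WINDOW
    b0 = int(round(w[0] / data.bin_width))
    b1 = int(round(w[1] / data.bin_width))
    cat = lambda d: core_data.category_of(d, data.boundary_deg)
    lines = ["neuron\trcti\trdsi"]
    for nid in data.neuron_ids:
        by_dir: dict[float, list[float]] = {}
        for t in data.trials_of(nid):
            by_dir.setdefault(t.theta_sample, []).append(float(t.counts[b0:b1].sum()))
        lines.append(f"{nid}\t{rcti(by_dir, cat):.4f}\t{rdsi(by_dir, cat):.4f}")
    Path(out).write_text("\n".join(lines) + "\n")
    click.echo(f"single-neuron metrics -> {out}")


if __name__ == "__main__":
    cli()
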