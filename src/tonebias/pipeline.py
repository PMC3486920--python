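"""End-to-end orchestration: simulate -> exclude -> fit -> analyze -> report.

A :class:`RunConfig` fully determines a run's outputs given the code
version: one master seed feeds block simulation, fit multistarts and the
permutation tests, and every output JSON carries the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import bias, fitting
from .io import write_json, write_trials
from .observers import make_observer, prior_for_design
from .simulate import apply_exclusions, blocks_to_frame, simulate_blocks
from .stimuli import BlockDesign

log = logging.getLogger("tonebias")


@dataclass
class RunConfig:
    experiment: str = "exp1"
    condition: str = "none"
    n_blocks: int = 50
    n_trials: int = 80
    bias_prob: float = 0.9
    observer: dict = field(
        default_factory=lambda: {"type": "imm", "sigma": 0.08, "gamma": 0.6}
    )
    K: int = 3
    n_boot: int = 200
    do_ln_fit: bool = True
    do_crossval: bool = False
    do_imm_fit: bool = True
    do_bayes_fit: bool = True
    n_perm: int = 2000
    n_bins: int = 10
    min_count: int = 50
    seed: int = 0
    outdir: str = "results/run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def design(self) -> BlockDesign:
        return BlockDesign(
            experiment=self.experiment,
            condition=self.condition,
            n_trials=self.n_trials,
            bias_prob=self.bias_prob,
        )

    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline and write all artifacts to the out dir."""
    if config.n_blocks < 1:
        raise ValueError("config.n_blocks must be positive")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.hash(), "seed": config.seed}
    design = config.design()

    log.info("stage: simulate (%d blocks)", config.n_blocks)
    blocks = simulate_blocks(
        design,
        lambda: make_observer(config.observer, design),
        config.n_blocks,
        config.seed,
    )
    kept, excl = apply_exclusions(blocks)
    if not kept:
        raise RuntimeError("simulate: every block failed the convergence rule")
    trials = blocks_to_frame(kept)
    write_trials(trials, outdir / "trials.tsv")
    eligible = trials[trials["analysis_eligible"]]

    report: dict[str, Any] = {
        **meta,
        "exclusions": {
            "n_total": excl.n_total,
            "n_kept": excl.n_kept,
            "n_dropped": excl.n_dropped,
        },
    }

    log.info("stage: fits")
    fits: dict[str, Any] = dict(meta)
    jnds = []
    for b in kept:
        try:
            jnds.append(fitting.staircase_jnd(b))
        except ValueError:
            pass
    fits["staircase_jnd"] = {
        "median_pct": float(np.median(jnds)) if jnds else None,
        "n_blocks": len(jnds),
    }
    psych = fitting.fit_psychometric_frame(eligible)
    fits["psychometric_all"] = {
        "slope": psych.slope_a,
        "jnd_pct": psych.jnd_pct,
        "n_trials": psych.n_trials,
        "capped": psych.capped,
    }
    codes = bias.region_codes(
        eligible["f1_hz"].to_numpy(), eligible["f2_hz"].to_numpy()
    )
    for name, code in (("bias_plus", 1), ("bias_minus", -1)):
        sub = eligible[codes == code]
        if len(sub) >= 20:
            f = fitting.fit_psychometric_frame(sub)
            fits[f"psychometric_{name}"] = {
                "slope": f.slope_a,
                "jnd_pct": f.jnd_pct,
                "n_trials": f.n_trials,
                "capped": f.capped,
            }
    if config.do_ln_fit:
        ln = fitting.fit_ln_model(
            eligible, K=config.K, n_boot=config.n_boot, seed=config.seed
        )
        fits["ln_model"] = ln.to_dict()
    if config.do_imm_fit or config.do_bayes_fit:
        prior_mean, prior_sd = prior_for_design(design)
        imm_rows, bayes_rows = [], []
        for block_id, g in trials.groupby("block_id"):
            if config.do_imm_fit:
                f = fitting.fit_imm(g)
                imm_rows.append((block_id, f.sigma, f.gamma, f.mse))
            if config.do_bayes_fit:
                f = fitting.fit_bayes(g, prior_mean, prior_sd)
                bayes_rows.append((block_id, f.sigma1, f.sigma2, f.mse))
        if imm_rows:
            arr = np.array([r[1:] for r in imm_rows])
            fits["imm"] = {
                "median_sigma": float(np.median(arr[:, 0])),
                "median_gamma": float(np.median(arr[:, 1])),
                "median_mse": float(np.median(arr[:, 2])),
                "n_blocks": len(imm_rows),
            }
        if bayes_rows:
            arr = np.array([r[1:] for r in bayes_rows])
            fits["bayes"] = {
                "median_sigma1": float(np.median(arr[:, 0])),
                "median_sigma2": float(np.median(arr[:, 1])),
                "median_mse": float(np.median(arr[:, 2])),
                "n_blocks": len(bayes_rows),
            }
    if config.do_crossval:
        cv = fitting.crossval_compare(eligible, K=config.K, seed=config.seed)
        fits["crossval"] = {
            "mean_mse": {k: float(v) for k, v in cv.mean_mse().items()},
            "p_naive_vs_full": cv.wilcoxon("naive", "full"),
            "p_past_l1_vs_full": cv.wilcoxon("past_l1", "full"),
        }
    write_json(fits, outdir / "fits.json")
    report["fits"] = fits

    log.info("stage: bias analysis")
    analysis: dict[str, Any] = dict(meta)
    stats_ = bias.region_performance(eligible, fisher=True)
    analysis["regions"] = {
        region: {
            "n": int(stats_[region]["n"]),
            "frac_correct": float(stats_[region]["frac_correct"]),
            "sem": float(stats_[region]["sem"]),
        }
        for region in ("bias_plus", "bias_minus", "straddle")
    }
    analysis["fisher_p"] = stats_.fisher_p
    perm = bias.permutation_test_accuracy(
        eligible, n_perm=config.n_perm, seed=config.seed
    )
    analysis["permutation_accuracy"] = {
        "p_value": perm.p_value,
        "observed_diff": perm.observed,
        "n_perm": perm.n_perm,
    }
    bmap = bias.bias_map(
        eligible, n_bins=config.n_bins, min_count=config.min_count
    )
    analysis["bias_map"] = {
        "bin_edges_hz": [float(x) for x in bmap.bin_edges],
        "counts": bmap.counts.astype(int).tolist(),
        "frac_correct": [
            [None if np.isnan(v) else float(v) for v in row]
            for row in bmap.frac_correct
        ],
    }
    write_json(analysis, outdir / "analysis.json")
    report["analysis"] = analysis

    summary = _summary_text(config, report)
    (outdir / "summary.txt").write_text(summary)
    log.info("pipeline complete -> %s", outdir)
    return report


def _summary_text(config: RunConfig, report: dict[str, Any]) -> str:
    reg = report["analysis"]["regions"]
    lines = [
        f"tonebias pipeline run (seed={config.seed}, hash={report['config_hash']})",
        f"experiment={config.experiment} condition={config.condition} "
        f"observer={config.observer}",
        f"blocks kept {report['exclusions']['n_kept']}"
        f"/{report['exclusions']['n_total']}",
        f"accuracy Bias+ {reg['bias_plus']['frac_correct']:.3f} "
        f"(n={reg['bias_plus']['n']}), "
        f"Bias- {reg['bias_minus']['frac_correct']:.3f} "
        f"(n={reg['bias_minus']['n']})",
        f"permutation p = {report['analysis']['permutation_accuracy']['p_value']:.4g}",
        f"overall psychometric JND = "
        f"{report['fits']['psychometric_all']['jnd_pct']:.2f}%",
    ]
    sj = report["fits"]["staircase_jnd"]["median_pct"]
    if sj is not None:
        lines.append(f"median staircase JND = {sj:.2f}%")
    return "\n".join(lines) + "\n"
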