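"""End-to-end pipeline: fit -> screen -> network -> (optional) dynamics.

Driven by a YAML/dict config, writing every stage artifact plus a JSON
manifest (config echo, seeds, file hashes, timings) so a run is fully
reproducible from the manifest alone.  Also home to the combinatorial
utility quantifying why exhaustively parameterizing interaction
combinations is infeasible: even a 10-species pool already has 45 pair,
120 triple and 210 quadruple combinations.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .community import CommunityMatrix, CovariateMatrix
from .inference import DEFAULT_PENALTY, fit_exact, fit_pseudolikelihood, fit_abundance
from .mrf import ENUMERATION_LIMIT
from .network import build_network, network_summary
from .null_models import screen_alpha, screen_beta

logger = logging.getLogger("consnet")

__all__ = ["PipelineConfig", "run_pipeline", "count_interaction_combinations"]


def count_interaction_combinations(S: int, k: int) -> int:
    """Number of distinct unordered k-species combinations in an
    S-species pool (k = 1 counts intraspecific terms).  Exact integer
    arithmetic; the motivating burden: C(10,2)=45, C(10,3)=120,
    C(10,4)=210."""
    if not (1 <= k <= S):
        raise ValueError(f"need 1 <= k <= S, got k={k}, S={S}")
    return math.comb(S, k)


@dataclass
class PipelineConfig:
    """Configuration of a full constructive-network run."""

    community_csv: str
    covariate_csv: str
    outdir: str
    fit_method: str = "auto"  # auto | exact_ml | pseudolikelihood | poisson | negbin
    penalty: float = DEFAULT_PENALTY
    screen: bool = True
    n_permutations: int = 199
    fdr: float = 0.05
    min_weight: float = 0.0
    seed: int = 0
    screen_alpha_links: bool = True
    dynamics: dict | None = None  # keys: beta_scale, alpha_scale, self_regulation,
    #                               r, N0, E0, t_max, dt, gamma, K_drive

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "community_csv": self.community_csv, "covariate_csv": self.covariate_csv,
            "outdir": self.outdir, "fit_method": self.fit_method, "penalty": self.penalty,
            "screen": self.screen, "n_permutations": self.n_permutations, "fdr": self.fdr,
            "min_weight": self.min_weight, "seed": self.seed,
            "screen_alpha_links": self.screen_alpha_links, "dynamics": self.dynamics,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _choose_method(data: CommunityMatrix, requested: str) -> str:
    if requested != "auto":
        return requested
    if data.mode == "abundance":
        return "poisson"
    return "exact_ml" if data.n_species <= min(ENUMERATION_LIMIT, 10) else "pseudolikelihood"


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the workflow and return the run manifest.

    Stages: fit, screen (skippable), network, dynamics (skippable).  A
    stage failure aborts with the stage named; artifacts written by
    earlier stages are retained.  With ``resume=True`` a stage whose
    artifacts already exist is reloaded instead of recomputed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "stages": {},
        "files": {},
        "timings_s": {},
    }
    t_total = time.time()

    for p in (config.community_csv, config.covariate_csv):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")

    data = cio.read_community_csv(config.community_csv)
    covars = cio.read_covariate_csv(config.covariate_csv).aligned_to(data.site_ids)
    method = _choose_method(data, config.fit_method)
    logger.info("pipeline start: %d sites, %d species, method=%s, seed=%d",
                data.n_sites, data.n_species, method, config.seed)

    # --- stage: fit ----------------------------------------------------
    t0 = time.time()
    stage = "fit"
    try:
        if resume and (outdir / "fit.json").exists():
            fit = cio.read_fit_result(outdir)
            logger.info("fit stage resumed from %s", outdir)
        else:
            if method == "exact_ml":
                fit = fit_exact(data, covars, penalty=config.penalty)
            elif method == "pseudolikelihood":
                fit = fit_pseudolikelihood(data, covars, penalty=config.penalty)
            elif method in ("poisson", "negbin"):
                fit = fit_abundance(data, covars, family=method)
            else:
                raise ValueError(f"unknown fit method {method!r}")
            paths = cio.write_fit_result(fit, outdir, seed=config.seed)
            manifest["files"].update(paths)
        manifest["stages"][stage] = "completed"
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        _finish(manifest, outdir, t_total)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    manifest["timings_s"][stage] = round(time.time() - t0, 3)

    # --- stage: screen --------------------------------------------------
    t0 = time.time()
    stage = "screen"
    bscreen = ascreen = None
    if config.screen and data.mode == "occurrence":
        try:
            screen_fit_method = fit.method if fit.method in ("exact_ml", "pseudolikelihood") \
                else "pseudolikelihood"
            bscreen = screen_beta(
                data, covars, fit_method=screen_fit_method,
                n_permutations=config.n_permutations, fdr=config.fdr,
                seed=config.seed, penalty=config.penalty,
            )
            bscreen.to_csv(outdir / "screen_beta.csv")
            manifest["files"]["screen_beta"] = str(outdir / "screen_beta.csv")
            if config.screen_alpha_links:
                ascreen = screen_alpha(
                    data, covars, fit_method=screen_fit_method,
                    n_permutations=config.n_permutations, fdr=config.fdr,
                    seed=config.seed + 1, penalty=config.penalty,
                )
            manifest["stages"][stage] = "completed"
        except Exception as exc:
            manifest["stages"][stage] = f"failed: {exc}"
            _finish(manifest, outdir, t_total)
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    else:
        manifest["stages"][stage] = "skipped"
    manifest["timings_s"][stage] = round(time.time() - t0, 3)

    # --- stage: network -------------------------------------------------
    t0 = time.time()
    stage = "network"
    try:
        net = build_network(
            fit.params, screen=bscreen, alpha_screen=ascreen,
            fdr=config.fdr, min_weight=config.min_weight,
        )
        net.provenance["fit_method"] = fit.method
        net.provenance["seed"] = config.seed
        net.to_graphml(outdir / "network.graphml")
        net.to_edge_tsv(outdir / "edges.tsv")
        summary = network_summary(net)
        (outdir / "network_summary.json").write_text(
            json.dumps(summary, indent=2, default=str) + "\n"
        )
        manifest["files"]["network_graphml"] = str(outdir / "network.graphml")
        manifest["files"]["edges_tsv"] = str(outdir / "edges.tsv")
        manifest["files"]["network_summary"] = str(outdir / "network_summary.json")
        manifest["stages"][stage] = "completed"
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        _finish(manifest, outdir, t_total)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    manifest["timings_s"][stage] = round(time.time() - t0, 3)

    # --- stage: dynamics -------------------------------------------------
    t0 = time.time()
    stage = "dynamics"
    if config.dynamics:
        try:
            from .dynamics import rescale_from_mrf, simulate

            dyn = dict(config.dynamics)
            spec = rescale_from_mrf(
                fit.params,
                beta_scale=dyn.get("beta_scale", 0.1),
                alpha_scale=dyn.get("alpha_scale", 0.1),
                self_regulation=dyn.get("self_regulation", 1.0),
                r=dyn.get("r"),
                gamma=dyn.get("gamma"),
                K_drive=dyn.get("K_drive"),
            )
            S, F = spec.n_species, spec.n_factors
            N0 = np.asarray(dyn.get("N0", np.full(S, 0.1)), dtype=float)
            E0 = np.asarray(dyn.get("E0", np.zeros(F)), dtype=float)
            traj = simulate(spec, N0, E0,
                            t_max=dyn.get("t_max", 100.0), dt=dyn.get("dt", 0.01))
            traj.to_csv(outdir / "trajectory.csv")
            manifest["files"]["trajectory"] = str(outdir / "trajectory.csv")
            manifest["stages"][stage] = "completed"
            manifest["dynamics_diverged"] = traj.diverged
        except Exception as exc:
            manifest["stages"][stage] = f"failed: {exc}"
            _finish(manifest, outdir, t_total)
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    else:
        manifest["stages"][stage] = "skipped"
    manifest["timings_s"][stage] = round(time.time() - t0, 3)

    _finish(manifest, outdir, t_total)
    return manifest


def _finish(manifest: dict, outdir: Path, t_total: float) -> None:
    import consnet

    manifest["version"] = getattr(consnet, "__version__", "unknown")
    manifest["numpy_version"] = np.__version__
    manifest["timings_s"]["total"] = round(time.time() - t_total, 3)
    manifest["hashes"] = {
        name: _sha256(Path(p)) for name, p in manifest["files"].items() if Path(p).exists()
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
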