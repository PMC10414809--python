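"""File I/O: community/covariate CSVs, fit results, screens, networks.

All CSVs use a fixed dialect (comma, UTF-8, '.' decimal) so artifacts
are byte-reproducible across locales.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .community import CommunityMatrix, CovariateMatrix
from .inference import FitResult
from .mrf import MarkovNetworkParams

__all__ = [
    "read_community_csv",
    "read_covariate_csv",
    "write_community_csv",
    "write_covariate_csv",
    "write_fit_result",
    "read_fit_result",
]


def read_community_csv(path, mode: str | None = None) -> CommunityMatrix:
    """Read a site-by-species CSV (first column ``site_id``); mode is
    auto-detected unless overridden."""
    return CommunityMatrix.from_csv(path, mode=mode)


def read_covariate_csv(path) -> CovariateMatrix:
    return CovariateMatrix.from_csv(path)


def write_community_csv(data: CommunityMatrix, path) -> None:
    data.to_csv(path)


def write_covariate_csv(covars: CovariateMatrix, path) -> None:
    covars.to_csv(path)


def write_fit_result(result: FitResult, outdir, seed=None) -> dict:
    """Serialize a fit: alpha.csv, beta.csv and a JSON sidecar.

    Returns the paths written (as strings) keyed by artifact name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = result.params
    alpha_path = outdir / "alpha.csv"
    beta_path = outdir / "beta.csv"
    pd.DataFrame(p.alpha, index=p.species_names, columns=p.factor_names).to_csv(
        alpha_path, index_label="species"
    )
    pd.DataFrame(p.beta, index=p.species_names, columns=p.species_names).to_csv(
        beta_path, index_label="species"
    )
    sidecar = {
        "method": result.method,
        "converged": result.converged,
        "final_objective": result.final_objective,
        "n_iterations": result.n_iterations,
        "penalty": result.extras.get("penalty"),
        "seed": seed,
        "warnings": result.warnings,
    }
    sidecar_path = outdir / "fit.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, default=str) + "\n")
    return {"alpha": str(alpha_path), "beta": str(beta_path), "sidecar": str(sidecar_path)}


def read_fit_result(outdir) -> FitResult:
    """Reload a serialized fit (params + sidecar metadata)."""
    outdir = Path(outdir)
    alpha = pd.read_csv(outdir / "alpha.csv", index_col="species")
    beta = pd.read_csv(outdir / "beta.csv", index_col="species")
    meta = json.loads((outdir / "fit.json").read_text())
    params = MarkovNetworkParams(
        alpha.to_numpy(), beta.to_numpy(), list(alpha.index), list(alpha.columns)
    )
    return FitResult(
        params=params,
        method=meta["method"],
        converged=bool(meta["converged"]),
        final_objective=float(meta["final_objective"]),
        n_iterations=int(meta["n_iterations"]),
        warnings=list(meta.get("warnings", [])),
        extras={"penalty": meta.get("penalty")},
    )
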