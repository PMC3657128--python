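"""Fit the hierarchical plot-effect model for one region and score it.

Loads the tables written by 01_generate_inventory.py, runs the MCMC for the
northern hardwoods region, and compares the posterior to the stored
generating truth: hyperparameter means, effect sds, and the correlation
structure.  Writes per-plot posterior summaries and hyperparameter estimates
under results/fit/.
"""

import json
import warnings
from pathlib import Path

import numpy as np

from forestvar.effects import FitConfig, fit_region
from forestvar.io import read_inventory
from forestvar.synthetic import SyntheticTruth

SEED = 20260921
ROOT = Path(__file__).resolve().parents[1] / "results"
REGION = "northern_hardwoods_hemlock"


def main() -> None:
    data = ROOT / "data"
    out = ROOT / "fit"
    out.mkdir(parents=True, exist_ok=True)
    tables = read_inventory(data / "trees.csv", data / "plots.csv")
    truth = SyntheticTruth.from_json((data / "truth.json").read_text())

    cfg = FitConfig(chains=2, draws=800, burn=800, seed=SEED % 2**31)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = fit_region(tables, REGION, cfg, truth.params)

    dist = truth.regions[REGION]
    mu_err = summary.mu_mean - dist.mu
    corr_err = summary.correlation_mean() - dist.correlation()
    print(f"region {REGION}: converged={summary.converged}")
    print(f"max |mu error|          : {np.abs(mu_err).max():.3f}")
    print(f"max |correlation error| : {np.abs(corr_err).max():.3f}")
    print(f"sigma_growth true/est   : {truth.params.sigma_growth:.3f} / "
          f"{summary.sigma_growth_mean:.3f}")

    summary.plot_effects.to_csv(out / "plot_effects.csv")
    (out / "hyper.json").write_text(json.dumps({
        "region": REGION,
        "seed": SEED,
        "mu": summary.mu_mean.tolist(),
        "sigma_mat": summary.sigma_mat_mean.tolist(),
        "sigma_growth": summary.sigma_growth_mean,
        "converged": summary.converged,
    }, indent=2))


if __name__ == "__main__":
    main()
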