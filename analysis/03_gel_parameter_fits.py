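#!/usr/bin/env python
"""Fit gel material parameters on synthetic embryo cohorts.

Generates noisy cohorts under the cytokinesis-like and pseudocleavage-like
study conditions, fits (tau, beta*tau, ell) with boundary values profiled
out, bootstraps over embryos for 68% intervals, probes tau identifiability
with boundary-only refits, and decomposes the fitted profile into its
mechanistic terms (compression, advection, diffusion, active).

Writes results/gel_fits.json and results/term_decomposition.csv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from nemacortex import studies
from nemacortex.datasets import average_datasets
from nemacortex.gel import (
    bootstrap_parameters,
    decompose_alignment_terms,
    fit_gel_parameters,
    identifiability_scan,
)
from nemacortex.synth import generate_embryo_dataset

OUT = Path(__file__).resolve().parents[1] / "results"
NOISE_SIGMA_Q = 0.02
N_EMBRYOS = 10
N_BOOT = 200


def fit_condition(name, truth, flow, myosin=None, include_lambda=False, seed=0):
    embryos = generate_embryo_dataset(truth, flow, myosin=myosin,
                                      noise_sigma_Q=NOISE_SIGMA_Q,
                                      n_embryos=N_EMBRYOS, seed=seed)
    avg = average_datasets(embryos)
    fit = fit_gel_parameters(avg, include_lambda=include_lambda)
    boot = bootstrap_parameters(embryos, n_boot=N_BOOT, seed=seed + 1,
                                include_lambda=include_lambda)
    summary = {
        "tau_report": fit.tau_report,
        "tau": fit.params.tau,
        "beta_tau": fit.params.beta_tau,
        "ell": fit.params.ell,
        "lambda_tau": fit.params.lambda_tau,
        "rss": fit.rss,
        "truth": {"tau": truth.tau, "beta_tau": truth.beta_tau,
                  "ell": truth.ell, "lambda_tau": truth.lambda_tau},
        "bootstrap_median": boot.median,
        "bootstrap_68ci": boot.interval,
    }
    print(f"{name}: tau = {fit.tau_report}, beta*tau = "
          f"{fit.params.beta_tau:.3f} min, ell = {fit.params.ell:.2f} um"
          + (f", lambda'tau = {fit.params.lambda_tau:.2f}"
             if include_lambda else ""))
    return avg, fit, summary


def main() -> None:
    OUT.mkdir(exist_ok=True)
    results = {}

    cyto_avg, cyto_fit, results["cytokinesis"] = fit_condition(
        "cytokinesis", studies.cytokinesis_truth(), studies.cytokinesis_flow(),
        seed=100,
    )
    pseudo_avg, pseudo_fit, results["pseudocleavage"] = fit_condition(
        "pseudocleavage", studies.pseudocleavage_truth(),
        studies.pseudocleavage_flow(), seed=200,
    )
    _, active_fit, results["cytokinesis_active"] = fit_condition(
        "cytokinesis+lambda", studies.cytokinesis_active_truth(),
        studies.cytokinesis_flow(), myosin=studies.cytokinesis_myosin(),
        include_lambda=True, seed=300,
    )

    # tau identifiability: convex residual valley for cytokinesis, flat
    # region below the detection bound for pseudocleavage
    grid = np.geomspace(0.05, 5.0, 41)
    scan_c = identifiability_scan(cyto_avg, "tau", grid, cyto_fit.params)
    scan_p = identifiability_scan(pseudo_avg, "tau", grid, pseudo_fit.params)
    results["tau_scan"] = {
        "grid_min": grid.tolist(),
        "cytokinesis_nrss": scan_c.normalized_rss.tolist(),
        "pseudocleavage_nrss": scan_p.normalized_rss.tolist(),
        "pseudocleavage_flat_bound": scan_p.flat_bound,
        "cytokinesis_flat_bound": scan_c.flat_bound,
    }
    print(f"tau scan: pseudocleavage residuals flat up to "
          f"{scan_p.flat_bound:.2f} min; cytokinesis has a localised "
          f"optimum (flat bound "
          f"{scan_c.flat_bound if scan_c.flat_bound else 'none'}).")

    # term decomposition for the lambda-enabled cytokinesis fit
    ds = generate_embryo_dataset(studies.cytokinesis_active_truth(),
                                 studies.cytokinesis_flow(),
                                 myosin=studies.cytokinesis_myosin())[0]
    terms = decompose_alignment_terms(active_fit.params, ds)
    pd.DataFrame({k: v for k, v in terms.items()}).to_csv(
        OUT / "term_decomposition.csv", index=False
    )
    peak_active = float(np.nanmax(terms["active"]))
    peak_comp = float(np.nanmax(terms["compression"]))
    results["term_peaks"] = {"active": peak_active, "compression": peak_comp}
    print(f"active-alignment peak {peak_active:.3f} vs compression peak "
          f"{peak_comp:.3f}: compression-based alignment dominates.")

    (OUT / "gel_fits.json").write_text(json.dumps(results, indent=2))


if __name__ == "__main__":
    main()
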