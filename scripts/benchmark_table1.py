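"""Long-running replicated benchmark of the fitting methods.

Runs the full simulate / 80-20 split / 4-fold CV / fit / evaluate
pipeline for the requested methods and replicate count, and prints the
aggregated error and selection metrics (relative model error against
the oracle refit, estimation error, uncured-probability bias and MSE,
support recovery).  At the reference scale (rho=0, 20+ replicates, the
full 50-point penalty path) this is a multi-hour job on one CPU; scale
it down with --replicates / --n-lambda for a quicker look.

Example:
    python scripts/benchmark_table1.py --v 0.5 --replicates 20 \
        --methods penMCFM-EM penMCFM-GMIFS MCM-GMIFS --out results/table_v05.csv
"""

from __future__ import annotations

import argparse
from pathlib import Path

from curefrail import BenchmarkConfig, EMControl, GMIFSControl, SimulationDesign, benchmark


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--v", type=float, default=0.5, help="signal magnitude")
    parser.add_argument("--rho", type=float, default=0.0)
    parser.add_argument("--replicates", "-M", type=int, default=20)
    parser.add_argument("--alpha-enet", type=float, default=0.5)
    parser.add_argument("--n-lambda", type=int, default=50)
    parser.add_argument("--k-adaptive", type=int, default=2)
    parser.add_argument(
        "--methods", nargs="+", default=["penMCFM-EM"],
        choices=["penMCFM-EM", "penMCFM-GMIFS", "MCM-GMIFS"],
    )
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=str, default=None)
    args = parser.parse_args()

    cfg = BenchmarkConfig(
        design=SimulationDesign(v=args.v, rho=args.rho),
        n_replicates=args.replicates,
        methods=tuple(args.methods),
        alpha_grid=(args.alpha_enet,),
        n_lambda=args.n_lambda,
        k_adaptive=args.k_adaptive,
        seed=args.seed,
        em_control=EMControl(tol=1e-4, max_iter=30, inner_max_iter=60),
        gmifs_control=GMIFSControl(max_steps=2000),
    )
    table = benchmark(cfg)
    if args.out:
        Path(args.out).parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(args.out, index=False)
    ok = table[~table["failed"]]
    cols = ["rme_beta_p", "err_beta_p", "rme_b_p", "err_b_p", "pi_bias", "pi_mse",
            "sensitivity_beta_p", "fpr_beta_p", "c_cure_test"]
    print(ok.groupby("method")[cols].agg(["mean", "std"]).round(3).to_string())


if __name__ == "__main__":
    main()
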