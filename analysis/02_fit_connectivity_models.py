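"""Fit the four connectivity formulations (UI, UV, DI, DV) to the data.

Each model is the same dynamic occupancy SPOM; they differ only in whether
connectivity weights source patches by their latent occupancy state
(U vs D) and whether dispersal parameters vary by year (I vs V).  Writes
per-model posterior draws and summary tables under results/fits/.

Chain settings here are analysis-scale (2 chains of 6,000 with half
discarded); production runs would use longer chains.

Run:  python analysis/02_fit_connectivity_models.py [--seed 1]
"""

import argparse
from pathlib import Path

from spomdyn.inference import MCMCConfig, fit_mcmc
from spomdyn.kernel import ModelSpec
from spomdyn.network import read_detection_history, read_patch_table

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--datadir", type=Path, default=Path("results/data"))
parser.add_argument("--outdir", type=Path, default=Path("results/fits"))
parser.add_argument("--iterations", type=int, default=6000)
args = parser.parse_args()

net = read_patch_table(args.datadir / "patches.csv")
hist = read_detection_history(args.datadir / "detections.csv", net)
args.outdir.mkdir(parents=True, exist_ok=True)

for label in ("UI", "UV", "DI", "DV"):
    model = ModelSpec.from_label(label)
    cfg = MCMCConfig(
        n_chains=2, n_iter=args.iterations, n_burnin=args.iterations // 2,
        thin=5, seed=args.seed,
    )
    post = fit_mcmc(hist, net, model, cfg)
    post.to_csv(args.outdir / f"posterior_{label}.csv")
    s = post.summary()
    s.to_csv(args.outdir / f"summary_{label}.csv")
    core = s.loc[["alpha", "beta", "delta0", "delta1", "psi1"]]
    print(f"\n=== {label} ===")
    print(core[["mean", "q2.5", "q97.5", "rhat"]].round(3).to_string())
print(f"\nposteriors and summaries in {args.outdir}")
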