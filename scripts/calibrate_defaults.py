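"""Recalibrate the default planted-effect attenuation table.

Iteratively measures the mean recovered Spearman rho of every default effect
over fresh synthetic cohorts (n = 78, full pipeline) and rescales each
(game, mechanism) attenuation factor by the measured-to-target ratio on the
latent scale. Prints the table to paste into ``swipescreen.cohort.ATTENUATION``.

Usage: python scripts/calibrate_defaults.py [--reps 100] [--iters 3] [--seed 11]
"""

from __future__ import annotations

import argparse
import math
from collections import defaultdict

import numpy as np

from swipescreen.cohort import (
    ATTENUATION,
    CohortConfig,
    DEFAULT_EFFECTS,
    measure_effects,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=100)
    ap.add_argument("--iters", type=int, default=3)
    ap.add_argument("--seed", type=int, default=11)
    args = ap.parse_args()

    lam = dict(ATTENUATION)
    targets = {}  # (game, feature, instrument) -> (mechanism, target)
    for spec in DEFAULT_EFFECTS:
        targets[(spec.game, spec.feature_name, spec.instrument)] = (
            spec.mechanism, spec.target_spearman)
    games = sorted({g for g, _, _ in targets})
    rng = np.random.default_rng(args.seed)

    for it in range(args.iters):
        print(f"\n=== iteration {it + 1} (reps={args.reps}) ===", flush=True)
        ratios = defaultdict(list)
        for game in games:
            pairs = [k for k in targets if k[0] == game]
            cfg = CohortConfig(attenuation=dict(lam))
            rhos = measure_effects(cfg, pairs, n_reps=args.reps,
                                   seed=int(rng.integers(0, 2 ** 31 - 1)),
                                   n_participants=78)
            for key in pairs:
                mech, target = targets[key]
                measured = float(rhos[key].mean())
                se = float(rhos[key].std(ddof=1) / math.sqrt(len(rhos[key])))
                ratio = math.sin(math.pi * measured / 6) / math.sin(math.pi * target / 6)
                ratios[(game, mech)].append(ratio)
                print(f"  {key}: target {target:+.3f}  measured {measured:+.3f} "
                      f"(se {se:.3f})  ratio {ratio:.3f}", flush=True)
        for gm, rs in ratios.items():
            lam[gm] = float(np.clip(lam[gm] * float(np.mean(rs)), 0.05, 1.5))
        print("  lambda ->", {k: round(v, 4) for k, v in lam.items()}, flush=True)

    print("\nATTENUATION = {")
    for k in sorted(lam):
        print(f"    {k!r}: {lam[k]:.4f},")
    print("}")


if __name__ == "__main__":
    main()
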