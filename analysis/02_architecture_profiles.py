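#!/usr/bin/env python
"""Radial architecture profiles of the simulated podosomes.

For each podosome written by 01_simulate_podosome.py: load the track table,
apply the 60 nm length filter, resample at 3 nm, estimate the core centre,
and bin orientation, point density, elastic-energy density (local weighting)
and filament length and strain (point-count weighting) in 25 nm radial bins.
Prints the core/surround contrasts; profile TSVs go to the run directories.
"""

from pathlib import Path

import numpy as np

from podomech import PipelineConfig, SyntheticPodosomeConfig, run_full

N_PODOSOMES = 4
OUT = Path(__file__).resolve().parent.parent / "results" / "podosomes"


def main() -> None:
    print("podosome  density in/out  energy in/out  orient in/out (deg)")
    for seed in range(1, N_PODOSOMES + 1):
        cfg = PipelineConfig(synthetic=SyntheticPodosomeConfig(seed=seed),
                             seed=seed)
        res = run_full(cfg, outdir=OUT / f"p{seed}")
        truth = res.ground_truth["core_radius_true_nm"]
        outer = res.ground_truth["config"]["outer_radius_nm"]

        def contrast(profile):
            rb, vb = profile.bin_centers_nm, profile.values
            return (np.nanmean(vb[rb < truth])
                    / np.nanmean(vb[(rb > truth) & (rb < outer)]))

        def in_out(profile):
            rb, vb = profile.bin_centers_nm, profile.values
            return (np.nanmean(vb[rb < truth]),
                    np.nanmean(vb[(rb > truth) & (rb < outer)]))

        o_in, o_out = in_out(res.profiles["orientation_deg"])
        print(f"   p{seed}       {contrast(res.profiles['density']):5.2f}"
              f"          {contrast(res.profiles['energy_density']):5.2f}"
              f"          {o_in:4.1f} / {o_out:4.1f}")
    print("\nexpected from the imaged networks: density contrast 2-3x, "
          "energy contrast 3-10x,\nsteep core (~47 deg) vs flat surround "
          "(~23 deg; point-wise means sit lower because\nchain wander "
          "regresses per-point angles toward the isotropic 33 deg).")


if __name__ == "__main__":
    main()
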