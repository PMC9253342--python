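#!/usr/bin/env python
"""Core radius and orientational correlation lengths.

Fits the four-parameter tanh transition m(r) = 1/2[(a+b) + (b-a)
tanh((r-r0)/rs)] to each podosome's orientation profile (r0 = core radius,
cross-checked against the density / length / energy fits) and the
exponential tangent-correlation model C(ds) = exp(-ds/lc) inside and
outside the fitted core.  lc well below the ~10 um thermal persistence
length indicates actively deformed filaments.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from podomech import PipelineConfig, SyntheticPodosomeConfig, run_full
from podomech.mechanics import MechanicsConstants

N_PODOSOMES = 4
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    for seed in range(1, N_PODOSOMES + 1):
        cfg = PipelineConfig(synthetic=SyntheticPodosomeConfig(seed=seed),
                             seed=seed)
        res = run_full(cfg, outdir=OUT / "podosomes" / f"p{seed}")
        cross = {k: (f.r0_nm if f.converged else np.nan)
                 for k, f in res.transition_fits.items()}
        rows.append({
            "podosome": f"p{seed}",
            "r_core_nm": res.r_core_nm,
            "r0_density_nm": cross.get("density"),
            "r0_length_nm": cross.get("length_nm"),
            "r0_energy_nm": cross.get("energy_density"),
            "lc_core_um": res.correlations["core"].lc_um,
            "lc_outside_um": res.correlations["outside"].lc_um,
        })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "core_radius_and_correlation.tsv", sep="\t", index=False,
              float_format="%.4g")
    print(df.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
    print("\nnote: the orientation fit is the designated core-radius "
          "estimator; the density and\nlength cross-checks can be captured "
          "by the outer extinction tail of the generation\ndomain, where "
          "the tanh model is misspecified, and scatter accordingly.")
    print(f"\nmean r_core = {df.r_core_nm.mean():.0f} nm "
          f"(generator truth 200 nm)")
    print(f"mean lc: core {df.lc_core_um.mean():.2f} um, outside "
          f"{df.lc_outside_um.mean():.2f} um (configured 1.68 / 2.41 um; "
          f"thermal ~{MechanicsConstants().persistence_length_um:.1f} um)")


if __name__ == "__main__":
    main()
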