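#!/usr/bin/env python
"""The force budget of the podosome core.

For each simulated podosome: total stored bending energy U_core, compressive
strain eps_core, core height h_core, the elastic force
F = U_core/(eps_core * h_core), the pressure P = F/(pi r_core^2), the
Young's modulus Y = P/eps_core with the volume-fraction cross-check
Y = Y_a phi^2, the balancing radial-meshwork tension
sigma = F/(2 pi r_core sin(theta_radial)), and the total
membrane-proximal polymerization force F_polym = f_a sum 1/sin(theta_i)
at the canonical 10 pN stall force and its 1 pN lower bound.

The headline contrast: F_polym stays below 1 nN while the elastic force is
tens of nN - polymerization pushing at the membrane cannot account for the
measured protrusion, stored network elasticity can.
"""

from pathlib import Path

import pandas as pd

from podomech import PipelineConfig, SyntheticPodosomeConfig, run_full

N_PODOSOMES = 4
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tables = []
    for seed in range(1, N_PODOSOMES + 1):
        cfg = PipelineConfig(synthetic=SyntheticPodosomeConfig(seed=seed),
                             seed=seed)
        res = run_full(cfg, outdir=OUT / "podosomes" / f"p{seed}")
        t = res.summary_table()
        t.insert(0, "podosome", f"p{seed}")
        tables.append(t)
    df = pd.concat(tables, ignore_index=True)
    df.to_csv(OUT / "core_mechanics_summary.tsv", sep="\t", index=False,
              float_format="%.5g")
    cols = ["podosome", "u_core_kbt", "eps_core", "h_core_nm",
            "f_elastic_nn", "p_kpa", "y_mpa", "sigma_mn_per_m",
            "n_protrusive", "f_polym_pn", "f_polym_1pn_pn", "u_polym_kbt"]
    print(df[cols].to_string(index=False, float_format=lambda x: f"{x:.3g}"))
    ratio = (df.f_elastic_nn / (df.f_polym_pn * 1e-3)).mean()
    print(f"\nelastic force exceeds the summed polymerization force "
          f"(10 pN stall) by ~{ratio:.0f}x on average;")
    print("the polymerization energy budget "
          f"(~{df.u_polym_kbt.mean():.2g} kBT) still exceeds the stored "
          f"elastic energy (~{df.u_core_kbt.mean():.2g} kBT), so "
          "polymerization can load the spring even though it cannot push "
          "the membrane directly.")


if __name__ == "__main__":
    main()
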