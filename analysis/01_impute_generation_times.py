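"""Fit the body-mass/generation-time allometry and impute fossil genera.

Fits the quadratic curve (used downstream), the linear regression and the
bivariate-normal EM on the packaged extant records, reports the raw-scale
correlations, and writes the completed trait table with imputed fossil
generation times.

Finding: the extant platyrrhine correlation is ~0.90 (15 genera) and the
extant study set gives ~0.91; the quadratic fit reproduces the reference
fossil generation times within +-1.5 yr for every fossil below 3 kg.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from platydate import datasets, traits

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

table = datasets.trait_table()
plat = traits.select_subset(table, "platyrrhini")
study = traits.select_subset(table, "study")

r_plat = traits.pearson_r(plat["body_mass_g"], plat["generation_time_yr"])
r_study = traits.pearson_r(study["body_mass_g"], study["generation_time_yr"])
print(f"Pearson r (extant platyrrhines, n={len(plat)}): {r_plat:.3f}")
print(f"Pearson r (study primates,      n={len(study)}): {r_study:.3f}")

fits = {
    "quadratic": traits.fit_quadratic(table, subset="platyrrhini"),
    "linear": traits.fit_linear(table, subset="platyrrhini"),
}
masked = table.copy()
masked.loc[masked["is_fossil"], "generation_time_yr"] = np.nan
completed_em, fits["em"] = traits.em_impute(masked)

rows = []
for name, fit in fits.items():
    rows.append(
        {
            "fit": name,
            "n_used": fit.n_used,
            "coefficients": np.array2string(
                np.asarray(fit.coefficients), precision=6
            ),
            "residual_sd_yr": round(fit.residual_sd, 3),
            "fitted_r": round(fit.fitted_r, 3),
        }
    )
pd.DataFrame(rows).to_csv(OUT / "allometry_fits.tsv", sep="\t", index=False)

imputed = traits.impute_generation_times(table, fits["quadratic"])
imputed.to_csv(OUT / "imputed_traits.csv", index=False)

fossil = imputed[imputed["is_fossil"]]
ref = table.set_index("genus")["generation_time_yr"]
dev = (fossil.set_index("genus")["generation_time_yr"] - ref[fossil["genus"]]).abs()
small = fossil["body_mass_g"].to_numpy() <= 3000
print(
    f"quadratic imputation vs reference fossil column: "
    f"max |dev| = {dev[small].max():.1f} yr over {small.sum()} fossils <= 3000 g"
)
print(f"wrote {OUT/'allometry_fits.tsv'} and {OUT/'imputed_traits.csv'}")
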