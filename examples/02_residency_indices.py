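"""Detection indices and nonparametric species comparisons.

DI_total is the fraction of monitored days an animal was detected;
DI_bay is the same numerator over the days up to its last in-bay
detection (residency while using the bay).  DI_total <= DI_bay always.
"""

import telemeshare as tm

sim = tm.simulate_detections(
    tm.Scenario(
        n_receivers=12,
        study_span=("2014-01-01", "2015-12-31"),
        n_individuals={
            ("A_japonicus", "adult"): 6,
            ("L_amia", "adult"): 6,
            ("C_taurus", "subadult"): 8,
            ("C_carcharias", "juvenile"): 8,
        },
        seed=3,
    )
)
dataset = tm.filter_dataset(sim.detections, sim.tags, sim.receivers, min_days=10)

indices = tm.detection_indices(dataset)
print("per-species mean detection indices:")
print(
    indices.groupby("species")[["di_total", "di_bay"]].mean().round(3).to_string()
)

result = tm.compare_groups(indices["di_bay"], indices["species"])
print(
    f"\nKruskal-Wallis on DI_bay across species: "
    f"chi2 = {result.statistic:.2f}, df = {result.df}, p = {result.p_value:.4f}"
)
print("\nDunn post hoc (Benjamini-Hochberg adjusted):")
print(result.posthoc.round(4).to_string(index=False))
print(
    "\nA small adjusted p for a pair means those two species have "
    "reliably different residency to the bay."
)
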