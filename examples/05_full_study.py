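"""The complete study on a synthetic cohort, end to end.

Simulates a small paired cohort with the default fatigue signatures and
runs the full pipeline: band-power statistics with a Kolmogorov–Smirnov
normality gate, sensitive-band selection by effect size, α-band
connectivity, thresholded network metrics with their Shapiro–Wilk-gated
paired tests and Bonferroni families, and Spearman correlations against
the VAS-F total score. Prints the human-readable report; expect the α
band selected, Eg/Eloc/Cp up, Lp down, and the NE gains concentrated in
the frontal-to-centro-parietal regions.
"""

from fatiguenet import PipelineConfig, SimulationConfig, run_study, simulate_cohort

cohort = simulate_cohort(
    SimulationConfig(n_subjects=10, duration=30.0, fs=250.0, seed=0))
report = run_study(cohort, PipelineConfig(n_null=20, seed=0))

print(report.to_text())
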