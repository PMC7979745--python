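"""Associate depletion scores with epigenomic signal and risk-SNP ORs,
and scan a sequence with a PWM.

A signal track is simulated with Pearson correlation 0.6 to a set of
region essentiality z-scores, maxima are extracted per region, and the
correlation is recovered; representative SNP odds ratios are compared
between top-quartile and remaining regions."""

import numpy as np
import pandas as pd

from crescreen import epigenome, simulate

rng = np.random.default_rng(1)
n = 200
regions = pd.DataFrame({
    "chrom": "chrS",
    "start": np.arange(n) * 500,
    "end": np.arange(n) * 500 + 400,
    "name": [f"r{i}" for i in range(n)],
})
z = rng.standard_normal(n)

track = simulate.simulate_signal_track(regions, z, rho=0.6, seed=1)
maxima = epigenome.extract_region_signal(track, regions)
scores = pd.Series(z, index=regions["name"])
corr = epigenome.correlate_depletion_epigenome(scores, maxima.to_frame("H3K27ac-like"))
row = corr.iloc[0]
print(f"signal vs score: Spearman r={row['spearman_r']:.3f} "
      f"(p={row['spearman_p']:.2g}{row['stars']}), RIN-regression "
      f"slope p={row['slope_p']:.2g}")

snps = pd.DataFrame({
    "chrom": "chrS",
    "position": regions["start"] + rng.integers(0, 400, n),
    "odds_ratio": np.exp(rng.normal(0.1, 0.15, n)) + 0.2 * (z > np.quantile(z, 0.75)),
})
rep = epigenome.representative_odds_ratios(regions, snps)
enr = epigenome.snp_or_enrichment(rep, {"screen": scores})
grp = enr["groups"]["top_screen"]
print(f"top-quartile OR median {grp['median_top']:.3f} vs rest "
      f"{grp['median_rest']:.3f} (rank-sum p={grp['ranksum_p']:.2g})")

pwm = epigenome.PWM(np.random.default_rng(42).random((4, 12)), name="ctcf-like")
seq = "".join(rng.choice(list("ACGT"), 500)) + pwm.consensus()
hits = epigenome.pwm_scan(seq, pwm, threshold=0.85)
print(f"PWM hits at >=85% similarity: {len(hits)} "
      f"(best score {hits['score'].max():.3f})")
print()
print("The recovered Spearman r reflects the planted signal-essentiality")
print("coupling; the OR shift mirrors risk SNPs concentrating in the most")
print("essential regulatory elements.")
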