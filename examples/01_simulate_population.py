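"""Simulate a purebred Duroc line plus a Duroc x native crossbreeding chain.

Builds the pedigree (DUC x KNP -> F1, F1 x DUC -> F2, F1 x F2 -> terminal
cross), gene-drops a SNP panel, and generates growth records under the
direct + social genetic model.  Prints the population structure and the
expected breed composition of the terminal crossbreds.
"""

from sgeblup import SimConfig, breed_composition, simulate_all

config = SimConfig(seed=42, n_snps=500)
ped, genotypes, phenotypes, truth = simulate_all(config)

print("pedigree by breed:")
print(ped.df["breed"].value_counts().to_string())
print(f"\nphenotyped records: {len(phenotypes)}")
print(phenotypes.groupby("population")["adg"].describe()[["count", "mean", "std"]])

comp = breed_composition(ped)
cross = comp[ped.df["breed"].to_numpy() == "CROSS"]
print(f"\nterminal crossbreds: {100 * cross['DUC'].mean():.1f}% DUC, "
      f"{100 * cross['KNP'].mean():.1f}% KNP genome expected")
print("(the 5/8 : 3/8 split follows from halving parental fractions along the chain)")
print(f"\naverage pen sizes: {truth.avg_pen_size}")
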