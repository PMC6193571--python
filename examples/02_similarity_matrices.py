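"""Build the four covariance structures used by the animal models.

A       additive relatedness from the pedigree (tabular method)
S_n     environmental similarity: 1 - d/max(d) over scaled environments
S_epi   epiallelic similarity: same kernel over methylation counts
S_c     social similarity: 1/(1 + geodesic distance) in the network
"""

import numpy as np

import pedvar as pv

config = pv.SimulationConfig(
    pedigree=pv.PedigreeConfig(n_generations=5, size_range=(50, 70)),
    grid=pv.GridSpec(25, 25),
)
pop = pv.simulate_population(config, seed=2)
mats = pv.build_all_matrices(pop)

for name, mat in mats.items():
    off = mat.values[~np.eye(len(mat), dtype=bool)]
    print(f"{name:4s}  {len(mat)} x {len(mat)}  "
          f"off-diagonal range [{off.min():.3f}, {off.max():.3f}]  "
          f"min eigenvalue {mat.min_eigenvalue():.2e}")

print("\nA has parent-offspring/full-sib entries of 0.5; the similarity")
print("matrices live in [0, 1] with unit diagonal and are repaired to be")
print("positive semidefinite so they can serve as covariance structures.")

# sibling pairs are more similar than random pairs in every matrix
ped = pop.pedigree.set_index("id")
ids = pop.phenotyped_ids
dams = ped.loc[ids, "dam"].to_numpy()
rng = np.random.default_rng(0)
sib_pairs = []
for d in np.unique(dams):
    members = np.where(dams == d)[0]
    if len(members) >= 2:
        sib_pairs.append((ids[members[0]], ids[members[1]]))
print("\nmean similarity, full sibs vs random pairs:")
for name in ("Sn", "Sepi", "Sc"):
    mat = mats[name]
    sib = np.mean([mat.loc(i, j) for i, j in sib_pairs])
    rnd = np.mean(
        [mat.loc(*rng.choice(ids, 2, replace=False)) for _ in range(500)]
    )
    print(f"  {name:4s}  sibs {sib:.3f}  random {rnd:.3f}")
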