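"""Monte-Carlo power of the local test across association strengths.

Reproduces a slice of the factorial simulation study: power of the
geographically weighted test (and the aspatial LCT baseline) as the
phenotype-gene spatial association moves from low (noise variance 50)
to high (0.1), holding other factors at the reduced desk scale —
10x10 grid, 100 genes, K = 2 sets, 99 permutations, 20 replicates.
"""

from gwlct.simulate import ScenarioSpec, estimate_power, scenario_grid

print(f"full factorial design: {len(scenario_grid())} scenarios\n")
print(f"{'pheno assoc':>12} {'variance':>9} {'GWLCT':>14} {'global LCT':>14}")
for label, v in [("low", 50.0), ("moderate", 5.0), ("high", 0.1)]:
    sc = ScenarioSpec(bandwidth=20, grid_side=10, n_genes=100, geneset_prob=0.3,
                      gene_assoc_variance=5.0, pheno_assoc_variance=v)
    g = estimate_power(sc, "gwlct", replicates=20, B=99, seed=2)
    l = estimate_power(sc, "global_lct", replicates=20, B=99, seed=2)
    print(f"{label:>12} {v:9.1f} {g['power']:7.3f}±{g['se']:.3f} "
          f"{l['power']:7.3f}±{l['se']:.3f}")

print("\nGWLCT power is the mean over replicates of the fraction of")
print("locations rejecting at alpha = 0.05; it rises steeply as the")
print("phenotype tracks the gene-set surface more tightly.")
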