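"""Build a bootstrapped NJ tree and transfer clade labels from landmarks.

Simulates a tiny family: two landmark-defined clades, a query that is a
noisy copy of one landmark, and a landmark-free pair mimicking a
species-specific clade. The query inherits its landmark's clade; the pair
is reported as a novel-clade candidate rather than being forced into the
nearest labelled clade.
"""

from mybfam.phylo import assign_clades, bootstrap_support, tree_bipartitions

alignment = {
    "AtLandmark1": "AAAAAAAAAAAAAAAAAAAA",
    "AtLandmark2": "AAAAAAAAAAAAAAAAAAAC",
    "VvLandmark1": "TTTTTTTTTTTTTTTTTTTT",
    "VvLandmark2": "TTTTTTTTTTTTTTTTTTTG",
    "query_copy":  "AAAAAAAAAAAAAAAAAACA",
    "query_new_a": "GGGGGGGGGGCCCCCCCCCC",
    "query_new_b": "GGGGGGGGGGCCCCCCCCCG",
}
landmark_map = {
    "AtLandmark1": ("C13", "S7"), "AtLandmark2": ("C13", "S7"),
    "VvLandmark1": ("C18", "S5"), "VvLandmark2": ("C18", "S5"),
}

tree = bootstrap_support(alignment, n_reps=1000, seed=4)
print("internal edges (bipartition -> bootstrap %):")
for bipartition, node in tree_bipartitions(tree).items():
    print("  ", sorted(bipartition), f"{node.support:.0f}")

for a in assign_clades(tree, landmark_map, support_threshold=50):
    if a.clade != "unassigned":
        print(f"{a.query_id}: clade {a.clade} ({a.subgroup}), "
              f"support {a.support:.0f}%, via {', '.join(a.landmarks)}")
    elif a.novel_group:
        print(f"{a.query_id}: novel-clade candidate with "
              f"{set(a.novel_group) - {a.query_id}}")
    else:
        print(f"{a.query_id}: unassigned")
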