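"""Annotate functional motifs and diagnostic residues.

Scans a synthetic flavonol-regulator-like protein for the C-terminal S7
motif (GRTxRSxMK, two mismatches tolerated) and the terminal SG7-2 site,
and reads the diagnostic residue at canonical domain position 89 that
separates anthocyanin-type (A) from proanthocyanidin-type (G) regulators.
"""

from mybfam import datasets
from mybfam.motifs import SG7_PATTERN, residue_diagnostics, scan_motif, scan_sg7_terminal
from mybfam.profiles import R2_CONSENSUS, R3_CONSENSUS
from mybfam.scan import ProteinRecord, classify_protein, extract_domain, scan_repeats

domain = R2_CONSENSUS + R3_CONSENSUS
protein = ProteinRecord("flavonol_like",
                        "M" + domain + "A" * 240 + "GRTSRWAMQ" + "AGSTWLLS")

(sg7,) = scan_motif(protein, SG7_PATTERN, max_mismatch=2)
print(f"S7 motif: {sg7.matched} at {sg7.start} with {sg7.mismatches} "
      "substitutions vs GRTxRSxMK (flavonol-regulator hallmark)")
sg72 = scan_sg7_terminal(protein)
print(f"SG7-2 terminal motif: {sg72.matched}, tier {sg72.tier} "
      "(2 = full WLLS match)")

profile_r2, profile_r3 = datasets.load_profiles()
classification = classify_protein(
    scan_repeats(protein, profile_r2, profile_r3), protein
)
diag = residue_diagnostics(extract_domain(classification, protein))
print(f"residues 44/60/89/98: "
      f"{diag.residues[44]}/{diag.residues[60]}/{diag.residues[89]}/{diag.residues[98]}"
      f" -> position-89 reading: {diag.interpretation_89}")
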