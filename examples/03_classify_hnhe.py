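"""Motif scanning and HNHE family classification against the packaged
references (synthetic stand-ins with the canonical catalytic geometry)."""

from heg_atlas import classify_hnhe, load_references, scan_hnh_motif

refs = load_references()

# the I-HmuI-like reference maps its own catalytic residues onto themselves
hit = scan_hnh_motif(refs["IHMU"].protein_seq, "I-HmuI-like reference")
print("motif on the I-HmuI-like reference:")
print(f"  span {hit.motif_span}, pattern {hit.matched_pattern}")
print(f"  catalytic map (reference pos -> query pos): {hit.catalytic_map}")

# an exact GVE2-like sequence is assigned to its family with full coverage
a = classify_hnhe(("query_gve2", refs["GVE2"].protein_seq), refs)
print(f"\nexact GVE2-like query: family={a.family}, "
      f"coverage={a.reference_coverage:.2f}, identity={a.pct_identity:.1f}%")

# a 45% N-terminal fragment loses the motif region and is called TRUNCATED
frag = refs["IHMU"].protein_seq[: int(0.45 * len(refs['IHMU'].protein_seq))]
t = classify_hnhe(("fragment", frag), refs)
print(f"45% fragment: family={t.family}, coverage={t.reference_coverage:.2f} "
      f"(below the 0.6 intact threshold)")
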