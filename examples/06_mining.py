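"""Mine a density-scored library for building-block patterns.

Hypergeometric Z-scores quantify which blocks are over- or underexpressed
in the densest molecules; per-block means and heteroatom weight-percent
profiles give the complementary global picture.
"""

from densiscreen import (block_density_stats, enrichment_segments,
                         enrichment_topfraction, heteroatom_profile,
                         make_fixture)

library, densities = make_fixture(seed=0, n_molecules=1000)
truth = densities[densities["source"] == "true"]

print("top-decile enrichment (positive z = overexpressed among the densest):")
for r in sorted(enrichment_topfraction(library, truth, q=0.10),
                key=lambda r: -r.z):
    print(f"  {r.block_id}: z={r.z:+6.2f}  (K={r.K}, k={r.k})")

print("\nper-block mean density:")
for s in sorted(block_density_stats(library, truth),
                key=lambda s: -s.mean_density):
    print(f"  {s.block_id}: {s.mean_density:7.1f} +/- {s.sd_density:.1f} kg/m^3 "
          f"(n={s.n_molecules})")

seg = enrichment_segments(library, truth, n_segments=10)
print("\nZ-score of the thiadiazole block across density deciles "
      "(low -> high density):")
print(" ", " ".join(f"{z:+.1f}" for z in seg.z_matrix["B7"]))

prof = heteroatom_profile(library, truth, "S", bin_width=0.10)
print("\nmean density by sulfur weight-percent bin:")
for lo, hi, c, m in zip(prof.bin_edges[:-1], prof.bin_edges[1:],
                        prof.counts, prof.mean_density):
    if c:
        print(f"  {lo:.0%}-{hi:.0%}: {m:7.1f} kg/m^3  (n={c})")
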