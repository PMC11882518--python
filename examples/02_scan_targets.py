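"""Scan a 3'UTR for miRNA seed-match sites and apply the retention filters.

Plants one site of every class into a synthetic UTR, scans it, prints each
site with its class and duplex energy, then shows which interactions
survive the class / energy / site-count filters.
"""

from bamir.io_formats import SequenceRecord
from bamir.synthetic_data import UTRSimSpec, simulate_utr_with_sites
from bamir.target_prediction import filter_interactions, scan_utr

mirna = SequenceRecord("mir-example", "AGCGUCACCGGUCAAGCUUU")
spec = UTRSimSpec(
    utr_length=260,
    planted_sites=(("8mer", 20), ("7mer-m8", 60), ("7mer-A1", 100),
                   ("6mer", 140), ("off-6mer", 180)),
    rng_seed=21,
)
utr, _ = simulate_utr_with_sites(mirna, spec)

sites = scan_utr(mirna, utr)
print(f"{len(sites)} sites found in a {len(utr.sequence)} nt UTR:")
for s in sites:
    print(f"  position {s.utr_position:4d}  {s.site_class:8s}  "
          f"{s.energy_kcal_mol:6.2f} kcal/mol")

table = filter_interactions(sites)
print("\nAfter filtering (drop 6mer/off-6mer, drop energy > -7 kcal/mol,")
print("drop UTRs with <2 retained sites):")
print(table.to_string(index=False) if len(table) else "  no interactions retained")
print("\nMore negative energies mean more stable miRNA:target duplexes;")
print("only 8mer/7mer sites at or below -7 kcal/mol count toward a target.")
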