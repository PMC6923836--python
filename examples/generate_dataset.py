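"""Generate a small labelled synthetic dataset and inspect its structure.

Prints one record per class with its per-residue labels: signal peptides
(S-run = M + n/h/c regions, then mature N residues), transmembrane
negatives (an interior T-helix) and soluble negatives (all N).
"""

from sigunet import SyntheticSpec, generate_dataset

spec = SyntheticSpec(n_sp=20, n_tm=10, n_other=10, seed=42)
records = generate_dataset(spec)

n_sp = sum(1 for r in records if r.is_sp)
n_tm = sum(1 for r in records if r.is_tm)
print(f"{len(records)} records: {n_sp} signal peptide, {n_tm} transmembrane, "
      f"{len(records) - n_sp - n_tm} soluble")

for cls, pick in (("sp", lambda r: r.is_sp),
                  ("tm", lambda r: r.is_tm),
                  ("other", lambda r: not r.is_sp and not r.is_tm)):
    rec = next(r for r in records if pick(r))
    print(f"\n>{rec.id}  ({cls})")
    print(rec.sequence[:60])
    print(rec.labels[:60])

# The S-run length is the signal peptide span (initiator M + 11..27 residues);
# the aligned label line is what the network is trained to reproduce.
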