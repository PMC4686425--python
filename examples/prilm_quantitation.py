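"""Scan a synthetic protein for Q/N-rich prion-like intervals and quantify them.

Plants one glutamine/asparagine-rich motif (40 residues, 60% Q/N) in a
Q/N-free background, locates it with the sliding-window scanner, tabulates
its composition, then disrupts it by Q/N-to-alanine mutation and shows the
scanner no longer finds it — mirroring the motif-disruption experiment.
"""

from kogbody import simulate as sim
from kogbody.prilm import composition_table, mutate_interval_to_alanine, scan_qn_windows

planted = sim.simulate_sequence(
    sim.SequenceSimSpec(length=300, motif_insertions=((120, 40, 0.6),), seed=7),
    seq_id="demo",
)
found = scan_qn_windows(planted.sequence, window_length=20, qn_threshold=0.4)
print("planted motif :", planted.motifs[0])
print("scanner found :", found[0])
print(composition_table([planted.sequence], found).to_string(index=False))

mutated = mutate_interval_to_alanine(planted.sequence, found[0])
print("\nafter Q/N->A mutation, scanner finds:",
      scan_qn_windows(mutated, window_length=20, qn_threshold=0.4) or "nothing")
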