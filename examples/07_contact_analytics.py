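"""Coordinate-level contact analytics on a scripted toy membrane.

Builds a toy protein approaching a flat lipid layer, detects the binding
event from the COM-distance series (threshold 4 length units, first 100
time units after binding discarded in real analyses; a short discard here),
counts per-species lipid contacts at the 0.7 cutoff, and computes the
normalized per-residue contact profile.
"""

import numpy as np

from anomemb import gen_toy_membrane_frames
from anomemb.contacts import (
    contact_series, com_distance_series, detect_binding,
    residue_contact_profile,
)

tm = gen_toy_membrane_frames(
    n_frames=40, n_residues=10, lipid_counts={"PIP3": 6, "PIP2": 9},
    bound_fraction=0.5, seed=9,
)

d = com_distance_series(tm.frames)
wins = detect_binding(d, dt=1.0, threshold=4.0, discard=3.0)
print(f"scripted binding frame: {tm.bind_frame}; detected window(s): {wins}")

cs = contact_series(tm.frames[tm.bind_frame:], ["PIP3", "PIP2"], cutoff=0.7)
for sp, stats in cs.summary().items():
    print(f"{sp}: mean contacts = {stats['mean']:.2f} +- {stats['sd']:.2f} "
          f"(scripted post-binding count: {tm.expected_contacts[sp]})")

prof = residue_contact_profile(tm.frames[tm.bind_frame:], "PIP3", 0.7)
top = np.argsort(prof)[::-1][:3]
print("top contacting residues (normalized):",
      {int(r): round(float(prof[r]), 2) for r in top})
# The most-contacted residue scores 1 by construction of the profile;
# in real systems this picks out the PIP-binding loop.
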