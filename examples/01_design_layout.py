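"""Build a stepped-wedge layout and inspect its treatment indicator structures.

A standard complete SW-CRT with Q sequences runs for J = Q + 1 periods; the
clusters of sequence q cross from control to treatment at the start of period
q + 1.  The same layout supports three treatment-effect parameterizations:
one sustained effect (IT), one effect per exposure time (ETI), or one effect
per calendar period with both arms observed (CTI).
"""

from swtime import Design, design_matrix, exposure_time, treatment_indicators

design = Design(I=6, J=4, K=30)  # 3 sequences, 2 clusters each
print(f"clusters={design.I}, periods={design.J}, sequences={design.Q}, "
      f"cell size K={design.K}")

print("\nexposure time s = max(j - q, 0) for each cluster x period:")
for i in range(1, design.I + 1):
    row = [exposure_time(design, i, j) for j in range(1, design.J + 1)]
    print(f"  cluster {i} (sequence {design.sequence_of(i)}): {row}")

print("\nETI indicators (cluster 1): one column per exposure time 1..J-1")
tab = treatment_indicators(design, "ETI")
print(tab[tab.cluster == 1].to_string(index=False))

for kind in ("IT", "ETI", "CTI"):
    Z, names = design_matrix(design, kind)
    print(f"\n{kind} fixed-effects matrix: {Z.shape[0]} rows x {Z.shape[1]} cols "
          f"({names[:-design.J]} + {design.J} period indicators)")

# The matrices are full rank; the calendar-time column for the final period is
# dropped at construction because every cluster is treated then, making it
# indistinguishable from the period effect.
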