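"""The 44-coefficient catalog: taxonomy, and what one comparison looks like.

Two small fingerprints are compared under a handful of coefficients to show
how the choice of measure changes the similarity value, especially in how
shared absences (the d count) are treated.
"""
from binfing import catalog_frame, contingency, evaluate, get_measure

df = catalog_frame()
print(df[["id", "name", "class", "metricity", "scaling"]].to_string(index=False))
print()
print("class counts: ", df["class"].value_counts().to_dict())
print("metricity counts:", df["metricity"].value_counts().to_dict())

# two 10-metabolite fingerprints sharing 3 presences and 4 absences
x = [1, 1, 1, 0, 0, 0, 0, 1, 1, 0]
y = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
counts = contingency(x, y)
print(f"\ncontingency counts a={counts.a} b={counts.b} c={counts.c} d={counts.d}")
for mid in ("SM", "JT", "RR", "BUB", "HD", "Yu"):
    m = get_measure(mid)
    print(f"  {mid:4s} ({m.class_name:17s}) s' = {evaluate(m, counts):.3f}")
# SM counts the 3 shared absences as evidence of similarity, JT ignores
# them, RR penalizes them, and BUB weights them geometrically — the same
# pair of samples can look quite different depending on the coefficient.
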