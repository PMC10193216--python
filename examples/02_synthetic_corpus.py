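"""Generate a synthetic labeled drug-mention corpus.

The generator emulates a pharmacovigilance corpus: drugs grouped into
therapeutic classes with class-structured fingerprints, four noncompliance
labels with realistic unequal proportions, and a coupling knob that ties
text similarity to structural similarity.  The printed label counts track
the configured proportions (NC-u/m 0.21, NC-s 0.07, G-u 0.38, G-m 0.34).
"""

import simtransfer as st

config = st.GeneratorConfig(n_drugs=8, n_classes=4, docs_per_drug=500, coupling=0.7, seed=42)
drugs = st.generate_drug_set(config)
corpus = st.generate_corpus(drugs, config)

print(f"{len(corpus)} documents over {len(drugs)} drugs")
counts = corpus.label_counts()
for label in st.LABELS:
    print(f"  {label:7s} {counts[label]:5d}  ({counts[label] / len(corpus):.3f})")

simmat = st.similarity_matrix_from_drugs(drugs)
same = [d.name for d in drugs if d.class_id == 0][:2]
other = [d.name for d in drugs if d.class_id == 1][0]
print(f"\nTanimoto {same[0]}-{same[1]} (same class):  {simmat.similarity(*same):.3f}")
print(f"Tanimoto {same[0]}-{other} (other class): {simmat.similarity(same[0], other):.3f}")

st.write_corpus(corpus, "corpus.jsonl")
print("\nwrote corpus.jsonl (one JSON document per line)")
print(corpus[0].text[:70] + "...")
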