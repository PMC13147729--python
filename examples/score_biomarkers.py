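"""Score candidate genes with the eight-indicator score of interest.

Loads the packaged indicator table of 28 autism-linked (predicted)
imprinted genes, sums the eight binary evidence indicators per gene, and
applies the selection rule: ICR-linked ASD genes are kept outright;
non-ICR genes need a score of at least 3; pseudogenes and genes supported
only by cross-reactive probes are dropped.
"""

from spermage import load_published_scorecard, score_of_interest, \
    select_biomarkers
from spermage.biomarker import INDICATOR_COLUMNS

cards = load_published_scorecard()
print("gene             score  (ICR Co Multi Top90 Ma Op Is Pr)")
for gene, row in cards.iterrows():
    vec = [int(row[c]) for c in INDICATOR_COLUMNS]
    print(f"{gene:15s}  {score_of_interest(vec)}      {vec}")

selected = select_biomarkers(cards, asd_genes=set(cards.index),
                             pseudogenes={"SLC26A10"},
                             crossreactive_only={"C6orf145"})
print(f"\nselected biomarkers ({len(selected)}):")
print(", ".join(selected))
# A score counts how many independent lines of evidence support the gene;
# the selection keeps every ICR-linked gene plus high-scoring others,
# minus the pseudogene (SLC26A10) and cross-reactive-only entries.
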