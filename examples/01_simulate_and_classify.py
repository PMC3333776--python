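"""Simulate a rhizosphere microarray cohort and classify gene specificity.

Generates 1,000 genes with planted specificity categories, hybridizes them on
synthetic two-color slides (each rhizosphere against a glucose-grown
baseline), processes the slides (background correction, MA transform, lowess
normalization, replicate t-statistics) and classifies every gene.  The
printed table compares called category counts against the planted truth.
"""

from collections import Counter

from rhizoclass import SimulationConfig, make_gene_calls
from rhizoclass.arrays import Contrast
from rhizoclass.pipeline import process_slides
from rhizoclass.simulate import RHIZOSPHERES, generate_slides, generate_truth

config = SimulationConfig(n_genes=1000, noise_sd_log2=0.25, seed=42)
truths = generate_truth(config)
design = [Contrast(r, "glucose") for r in RHIZOSPHERES]
slides = generate_slides(truths, design, config)
results = process_slides(slides, design)

calls = make_gene_calls(
    {c.numerator: table for c, table in results.items()},
    replicon_map={t.gene_id: t.replicon for t in truths},
)

planted = Counter(t.category for t in truths)
called = Counter(c.category for c in calls)
print(f"{'category':<20}{'planted':>8}{'called':>8}")
for category in sorted(planted | called):
    print(f"{category:<20}{planted[category]:>8}{called[category]:>8}")

accuracy = sum(
    c.category == t.category for c, t in zip(calls, sorted(truths, key=lambda t: t.gene_id))
) / len(calls)
print(f"\nper-gene category accuracy: {accuracy:.3f}")
print(
    "Called counts track the planted truth; residual disagreement comes from\n"
    "replicate noise pushing borderline folds across the 2x/3x thresholds."
)
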