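"""Bundled gene sets used throughout the pipeline.

The shipped GMT (``data/genesets_synthetic.gmt``) is a synthetic stand-in:
it preserves the cardinalities the analysis depends on (58 UPR genes, the
four branch subsets, 33 RIDD targets, the 10-gene P53-repressed signature,
the two cytolytic-activity genes, and three non-oncogenic control pathways)
and uses real human gene symbols, but branch memberships are illustrative
rather than a faithful copy of the curated pathway databases. The synthetic
cohort generator draws its gene universe from these sets, so all internal
analyses are self-consistent.
"""

from __future__ import annotations

from importlib import resources

from aneupr.io import GeneSetCollection, read_gmt

UPR_SET = "UPR_58"
BRANCHES = ("PERK", "XBP1S", "ATF6", "RIDD_33")
RIDD_SET = "RIDD_33"
TP53_SET = "TP53_REPRESSED_10"
CYT_SET = "CYT"
CONTROL_SETS = (
    "CONTROL_OLFACTION",
    "CONTROL_CARDIAC_CONDUCTION",
    "CONTROL_PHOTOTRANSDUCTION",
)

#: Genes excluded from the single-cell RIDD comparison: their expression
#: behaves counter to degradation by IRE1alpha endonuclease activity.
SC_RIDD_EXCLUDE = ("ITGB2", "TAPBP")


def load_default_genesets() -> GeneSetCollection:
    """Load the bundled gene-set collection."""
    ref = resources.files("aneupr.data").joinpath("genesets_synthetic.gmt")
    with resources.as_file(ref) as path:
        return read_gmt(path)
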