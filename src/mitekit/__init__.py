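"""mitekit: mining, annotation and evolutionary analysis of MITE families.

A MITE (miniature inverted-repeat transposable element) is a short,
non-coding class II element bounded by terminal inverted repeats and
flanked by a target site duplication. This package mines copies of a
reference element from genome sequence, annotates their TIR/TSD
structure, reconstructs a family consensus, quantifies within- and
between-species divergence, builds bootstrap-supported
neighbor-joining trees, assigns hAT family membership from the TSD
consensus, and predicts PCR products for screening primers. A
synthetic-genome generator with full ground truth makes every stage
testable end to end.
"""

from importlib import resources

from .seqio import SequenceRecord, GenomicInterval, read_fasta, write_fasta, revcomp
from .mining import MiningParams, ElementCopy, mine_copies, find_seeds, extend_and_chain
from .annotate import (
    detect_tir, detect_tsd, classify_copy, orf_scan, gene_context, annotate_copies,
)
from .consensus import (
    StackedAlignment, global_align, stack_on_reference, majority_consensus,
)
from .divergence import p_distance, group_divergence, overall_mean_divergence
from .phylogeny import t92_distance, nj_tree, bootstrap_support, PhyloTree
from .tsd import build_pfm, call_consensus, classify_family
from .pcr import find_primer_sites, predict_amplicons, MAR_F, MAR_R
from .simulate import SimulationParams, plant_copies, mutate_copy, simulate_species_set

__version__ = "0.1.0"


def load_synthetic_reference() -> SequenceRecord:
    """Load the bundled synthetic reference element.

    This is a constructed stand-in for the canonical 610-bp element:
    it carries the family's structural constants (11-bp TIRs matching
    the CAG(G/A)GGTAGGC consensus, an AT-rich interior, and the
    MarF/MarR primer sites spaced to yield the expected 455-bp PCR
    product) over an otherwise synthetic backbone. It is not the
    GenBank sequence.
    """
    path = resources.files("mitekit.data").joinpath("mar_reference_synthetic.fasta")
    with resources.as_file(path) as p:
        return read_fasta(p)[0]
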