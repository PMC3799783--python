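"""Published reference results for the GSE2240 atrial-fibrillation study.

The original asymmetric-PCA analysis of GEO accession GSE2240 (U133A
platform, 10 permanent-AF cases vs 20 sinus-rhythm controls, one
duplicated control array) reported per-probe discriminant scores for
the 63 probe sets that passed the threshold, mapping to 51 gene
symbols. That published score table is shipped here as a small TSV so
the downstream calling and aggregation machinery can be exercised on
real reported numbers without downloading the accession.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Sample bookkeeping of the GSE2240 U133A design.
GSE2240_N_SAMPLES = 30
GSE2240_N_INDEPENDENT = 29
GSE2240_N_CONTROLS_INDEPENDENT = 19
GSE2240_N_CASES = 10


def load_reference_scores() -> pd.DataFrame:
    """Load the published per-probe discriminant scores.

    Returns a score table with columns ``gene_no`` (the published gene
    numbering), ``gene_symbol`` (verbatim, including composite loci
    such as ``"HBA1 /// HBA2"``), ``probe_id`` and ``score``.
    """
    path = resources.files("apca.data") / "gse2240_deg_scores.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype={"gene_no": int})
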