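"""Published per-gene transcriptome/translatome calls bundled as data.

The APP/PS1 high-fat-diet study reported, for each of its three adjacent
contrasts (Nor vs AD, AD vs AD_HFD, AD_HFD vs H_H), the named genes that
changed at both the transcriptional and translational level, split into
both-up, both-down, and the two opposite quadrants. This table is an
input for the joint quadrant classifier; it lets the classifier be
checked against the study's printed both-level totals (25, 19 and 18
genes).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = "joint_calls_appps1_hfd.tsv"


def load_joint_calls() -> pd.DataFrame:
    """Columns: contrast, gene, rna_call, ribo_call."""
    with resources.files("ribolens").joinpath("data", _DATA).open() as fh:
        return pd.read_csv(fh, sep="\t")


def calls_to_de_tables(calls: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand published calls into minimal per-layer DE tables.

    Statistics are placeholders consistent with the call (a significant
    gene gets p below and |log2fc| above the default thresholds); only
    direction/significance matter to the quadrant classifier.
    """
    def table(col: str) -> pd.DataFrame:
        sig = calls[col] != "ns"
        lfc = calls[col].map({"up": 1.0, "down": -1.0, "ns": 0.0})
        df = pd.DataFrame({
            "base_mean": 100.0,
            "log2fc": lfc,
            "se": 0.2,
            "p": sig.map({True: 1e-3, False: 0.5}),
            "q": sig.map({True: 1e-2, False: 0.6}),
            "significant": sig,
            "direction": calls[col],
        })
        df.index = pd.Index(calls["gene"], name="gene_id")
        return df

    return table("rna_call"), table("ribo_call")
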