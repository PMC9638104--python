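"""Sample sheets: samples, ordered groups, omics layers, replicates."""

from __future__ import annotations

import pandas as pd


class DesignError(ValueError):
    """Sample sheet violates the experimental-design contract."""


class SampleDesign:
    """Mapping of samples to ordered condition groups within omics layers.

    Group order is taken from first appearance in the sheet (Nor < AD <
    AD_HFD < H_H is semantic, not lexical); trend profiling depends on it.
    """

    COLUMNS = ("sample_id", "group", "layer", "replicate")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise DesignError(f"sample sheet missing columns: {sorted(missing)}")
        table = table.loc[:, list(self.COLUMNS)].copy()
        table["replicate"] = table["replicate"].astype(int)
        if (table["replicate"] < 1).any():
            raise DesignError("replicate indices must be >= 1")
        for layer, sub in table.groupby("layer", sort=False):
            if sub["sample_id"].duplicated().any():
                dups = sub.loc[sub["sample_id"].duplicated(), "sample_id"].tolist()
                raise DesignError(f"duplicate sample ids in layer {layer}: {dups}")
        self.table = table.reset_index(drop=True)
        # ordered by first appearance
        self.groups = list(dict.fromkeys(table["group"]))
        self.layers = list(dict.fromkeys(table["layer"]))

    def samples(self, layer: str, group: str | None = None) -> list[str]:
        sub = self.table[self.table["layer"] == layer]
        if group is not None:
            sub = sub[sub["group"] == group]
        return sub["sample_id"].tolist()

    def group_of(self, layer: str) -> pd.Series:
        """sample_id -> group for one layer."""
        sub = self.table[self.table["layer"] == layer]
        return sub.set_index("sample_id")["group"]

    def subset(self, layer: str) -> "SampleDesign":
        return SampleDesign(self.table[self.table["layer"] == layer])

    def require_replicates(self, layer: str, groups: list[str], n_min: int = 2) -> None:
        for g in groups:
            n = len(self.samples(layer, g))
            if n < n_min:
                raise DesignError(
                    f"group {g!r} has {n} sample(s) in layer {layer!r}; "
                    f"need >= {n_min} for statistical operations")

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleDesign) and self.table.equals(other.table)

    @classmethod
    def build(cls, groups, reps: int, layers) -> "SampleDesign":
        """Balanced design: ``{group}_{layer}_{rep}`` sample ids."""
        rows = [
            {"sample_id": f"{g}_{layer}_{r}", "group": g, "layer": layer,
             "replicate": r}
            for layer in layers for g in groups for r in range(1, reps + 1)
        ]
        return cls(pd.DataFrame(rows))
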