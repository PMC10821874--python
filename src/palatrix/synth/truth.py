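"""Ground-truth bundle emitted next to each simulated dataset."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from palatrix.config import SimConfig
from palatrix.synth.program import RegulatoryProgram


@dataclass
class GroundTruth:
    """Planted truth for parameter-recovery tests.

    Carries the serializable part of the regulatory program (links, TF->target
    edges, TF programs, proliferation set, branch weights, config) plus the
    per-cell state table.  Round-trips losslessly through JSON.
    """

    config: SimConfig
    states: pd.DataFrame
    links: pd.DataFrame
    edges: pd.DataFrame
    tf_programs: pd.DataFrame
    prolif_genes: list
    branch_weights: list

    # ------------------------------------------------------------------ io
    def to_json(self) -> str:
        payload = {
            "config": self.config.to_dict(),
            "states": {
                "index": list(self.states.index),
                "columns": list(self.states.columns),
                "data": [[None if (isinstance(v, float) and np.isnan(v)) else v
                          for v in row]
                         for row in self.states.itertuples(index=False)],
            },
            "links": self.links.to_dict(orient="list"),
            "edges": self.edges.to_dict(orient="list"),
            "tf_programs": {
                "index": list(self.tf_programs.index),
                "columns": list(self.tf_programs.columns),
                "data": [list(r) for r in self.tf_programs.itertuples(index=False)],
            },
            "prolif_genes": list(self.prolif_genes),
            "branch_weights": [float(w) for w in self.branch_weights],
        }
        return json.dumps(payload, default=_json_scalar)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        states = pd.DataFrame(d["states"]["data"], columns=d["states"]["columns"],
                              index=pd.Index(d["states"]["index"], name="barcode"))
        states["branch"] = states["branch"].astype(int)
        for col in ("s", "g_true", "rna_depth", "atac_depth"):
            states[col] = states[col].astype(float)
        tfp = pd.DataFrame(d["tf_programs"]["data"],
                           columns=d["tf_programs"]["columns"],
                           index=pd.Index(d["tf_programs"]["index"], name="tf"))
        return cls(
            config=SimConfig.from_dict(d["config"]),
            states=states,
            links=pd.DataFrame(d["links"]),
            edges=pd.DataFrame(d["edges"]),
            tf_programs=tfp,
            prolif_genes=list(d["prolif_genes"]),
            branch_weights=list(d["branch_weights"]),
        )

    def terminal_branch(self) -> pd.Series:
        """Branch label per cell (-1 for multipotent)."""
        return self.states["branch"]


def _json_scalar(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def make_ground_truth(program: RegulatoryProgram, states: pd.DataFrame) -> GroundTruth:
    return GroundTruth(
        config=program.config,
        states=states,
        links=program.links.copy(),
        edges=program.edges.copy(),
        tf_programs=program.tf_programs.reset_index().set_index("tf"),
        prolif_genes=list(program.prolif_genes),
        branch_weights=[float(w) for w in program.config.branch_probs()],
    )
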