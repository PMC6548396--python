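"""Actor/partner effect decomposition of the APIMeM.

For each role (patient, nearest relative) and each pathway type (actor:
own support -> own functioning; partner: own support -> the other member's
functioning) the decomposition yields a direct effect, two simple indirect
effects through the two mediators, their sum (the total indirect effect) and
the total effect:

    patient   actor   total = a_A1*b_A1 + a_P2*b_P1 + cp_A1
    relative  actor   total = a_A2*b_A2 + a_P1*b_P2 + cp_A2
    patient   partner total = a_A2*b_P1 + a_P1*b_A1 + cp_P1
    relative  partner total = a_A1*b_P2 + a_P2*b_A2 + cp_P2

with the total indirect effect the first two terms of each sum.  The identity
``total = direct + total indirect`` holds exactly.  :func:`enumerate_paths`
provides an independent brute-force check by multiplying edge weights along
every directed route of the six-node path diagram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import pandas as pd

from .errors import UndefinedStatisticError
from .estimate import PathCoefficients

ROLE_LABEL = {"patient": "Patient", "relative": "Nearest relative"}


@dataclass(frozen=True)
class PathwayEffects:
    """One role x pathway cell of the decomposition."""

    role: str          # "patient" | "relative"
    pathway: str       # "actor" | "partner"
    total: float
    total_ie: float
    simple_ies: Mapping[str, float]   # label -> value (two entries)
    direct: float


@dataclass(frozen=True)
class EffectTable:
    cells: tuple

    def get(self, role: str, pathway: str) -> PathwayEffects:
        for c in self.cells:
            if c.role == role and c.pathway == pathway:
                return c
        raise KeyError((role, pathway))

    def as_frame(self) -> pd.DataFrame:
        """Long-format table mirroring the published layout: one row per
        (role, pathway, effect kind)."""
        rows = []
        for c in self.cells:
            prefix = f"{ROLE_LABEL[c.role]} {c.pathway}"
            rows.append({"role": c.role, "pathway": c.pathway,
                         "effect": "Total effect", "label": f"{prefix} total effect",
                         "estimate": c.total})
            rows.append({"role": c.role, "pathway": c.pathway,
                         "effect": "Total IE", "label": f"{prefix} total IE",
                         "estimate": c.total_ie})
            for lbl, v in c.simple_ies.items():
                rows.append({"role": c.role, "pathway": c.pathway,
                             "effect": "Simple IE", "label": lbl, "estimate": v})
            rows.append({"role": c.role, "pathway": c.pathway,
                         "effect": "Direct effect", "label": f"{prefix} direct effect",
                         "estimate": c.direct})
        df = pd.DataFrame(rows)
        df["estimate_3dp"] = df["estimate"].round(3)
        return df

    def flat(self) -> dict:
        """label -> estimate for every quantity in the table."""
        out = {}
        for _, row in self.as_frame().iterrows():
            out[row["label"]] = row["estimate"]
        return out


def decompose(paths: PathCoefficients | Mapping[str, float]) -> EffectTable:
    """Compute all twenty effects of the decomposition from the twelve paths."""
    if not isinstance(paths, PathCoefficients):
        paths = PathCoefficients.from_dict(dict(paths))
    d = paths.as_dict()

    cells = (
        PathwayEffects(
            role="patient", pathway="actor",
            total=d["a_A1"] * d["b_A1"] + d["a_P2"] * d["b_P1"] + d["cp_A1"],
            total_ie=d["a_A1"] * d["b_A1"] + d["a_P2"] * d["b_P1"],
            simple_ies={
                "Patient actor-actor IE": d["a_A1"] * d["b_A1"],
                "Patient partner-partner IE": d["a_P2"] * d["b_P1"],
            },
            direct=d["cp_A1"],
        ),
        PathwayEffects(
            role="relative", pathway="actor",
            total=d["a_A2"] * d["b_A2"] + d["a_P1"] * d["b_P2"] + d["cp_A2"],
            total_ie=d["a_A2"] * d["b_A2"] + d["a_P1"] * d["b_P2"],
            simple_ies={
                "Nearest relative actor-actor IE": d["a_A2"] * d["b_A2"],
                "Nearest relative partner-partner IE": d["a_P1"] * d["b_P2"],
            },
            direct=d["cp_A2"],
        ),
        PathwayEffects(
            role="patient", pathway="partner",
            total=d["a_A2"] * d["b_P1"] + d["a_P1"] * d["b_A1"] + d["cp_P1"],
            total_ie=d["a_A2"] * d["b_P1"] + d["a_P1"] * d["b_A1"],
            simple_ies={
                "Patient actor-partner IE": d["a_A2"] * d["b_P1"],
                "Patient partner-actor IE": d["a_P1"] * d["b_A1"],
            },
            direct=d["cp_P1"],
        ),
        PathwayEffects(
            role="relative", pathway="partner",
            total=d["a_A1"] * d["b_P2"] + d["a_P2"] * d["b_A2"] + d["cp_P2"],
            total_ie=d["a_A1"] * d["b_P2"] + d["a_P2"] * d["b_A2"],
            simple_ies={
                "Nearest relative actor-partner IE": d["a_A1"] * d["b_P2"],
                "Nearest relative partner-actor IE": d["a_P2"] * d["b_A2"],
            },
            direct=d["cp_P2"],
        ),
    )
    return EffectTable(cells=cells)


#: fixed label order of the twenty decomposition quantities
EFFECT_LABELS = (
    "Patient actor total effect", "Patient actor total IE",
    "Patient actor-actor IE", "Patient partner-partner IE",
    "Patient actor direct effect",
    "Nearest relative actor total effect", "Nearest relative actor total IE",
    "Nearest relative actor-actor IE", "Nearest relative partner-partner IE",
    "Nearest relative actor direct effect",
    "Patient partner total effect", "Patient partner total IE",
    "Patient actor-partner IE", "Patient partner-actor IE",
    "Patient partner direct effect",
    "Nearest relative partner total effect", "Nearest relative partner total IE",
    "Nearest relative actor-partner IE", "Nearest relative partner-actor IE",
    "Nearest relative partner direct effect",
)


def effect_values(d: Mapping[str, float]) -> "np.ndarray":
    """The twenty effects in :data:`EFFECT_LABELS` order, computed directly
    from a path-name -> value mapping.  Fast path used inside resampling
    loops; agrees with :func:`decompose` exactly."""
    import numpy as np

    aa1 = d["a_A1"] * d["b_A1"]; pp1 = d["a_P2"] * d["b_P1"]
    aa2 = d["a_A2"] * d["b_A2"]; pp2 = d["a_P1"] * d["b_P2"]
    ap1 = d["a_A2"] * d["b_P1"]; pa1 = d["a_P1"] * d["b_A1"]
    ap2 = d["a_A1"] * d["b_P2"]; pa2 = d["a_P2"] * d["b_A2"]
    return np.array([
        aa1 + pp1 + d["cp_A1"], aa1 + pp1, aa1, pp1, d["cp_A1"],
        aa2 + pp2 + d["cp_A2"], aa2 + pp2, aa2, pp2, d["cp_A2"],
        ap1 + pa1 + d["cp_P1"], ap1 + pa1, ap1, pa1, d["cp_P1"],
        ap2 + pa2 + d["cp_P2"], ap2 + pa2, ap2, pa2, d["cp_P2"],
    ])


# edges of the six-node path diagram: (source, sink) -> path name
_EDGES = {
    ("x1", "m1"): "a_A1", ("x2", "m1"): "a_P1",
    ("x2", "m2"): "a_A2", ("x1", "m2"): "a_P2",
    ("m1", "y1"): "b_A1", ("m2", "y1"): "b_P1",
    ("m2", "y2"): "b_A2", ("m1", "y2"): "b_P2",
    ("x1", "y1"): "cp_A1", ("x2", "y1"): "cp_P1",
    ("x2", "y2"): "cp_A2", ("x1", "y2"): "cp_P2",
}


def enumerate_paths(paths: PathCoefficients, source: str, sink: str) -> list:
    """Brute-force enumeration of all directed routes source -> sink in the
    structural diagram, each with the product of its edge weights.

    The sum over routes with at least one intermediate node equals the total
    indirect effect for that (source, sink) pair; the one-edge route equals
    the direct effect.  Serves as the independent oracle for :func:`decompose`.
    """
    d = paths.as_dict()
    g = nx.DiGraph()
    for (u, v), name in _EDGES.items():
        g.add_edge(u, v, weight=d[name], name=name)
    out = []
    for route in nx.all_simple_paths(g, source, sink):
        prod = 1.0
        for u, v in zip(route, route[1:]):
            prod *= g.edges[u, v]["weight"]
        out.append((tuple(route), prod))
    return out


def proportion_mediated(
    table: EffectTable,
    role: str,
    pathway: str = "actor",
    numerator: str = "actor-actor",
) -> float:
    """Percentage of a pathway's total effect carried by an indirect route.

    ``numerator`` selects the simple IE of interest: ``"actor-actor"`` /
    ``"actor-partner"`` (keyed by the suffix of the simple-IE label) or
    ``"total_ie"`` for the summed indirect effect.  Values outside [0, 100]
    (inconsistent mediation) are returned as-is with a warning, never clamped.
    """
    cell = table.get(role, pathway)
    if cell.total == 0:
        raise UndefinedStatisticError(
            f"proportion mediated undefined: zero total effect for {role} {pathway}"
        )
    if numerator == "total_ie":
        num = cell.total_ie
    else:
        matches = [v for lbl, v in cell.simple_ies.items() if lbl.endswith(f"{numerator} IE")]
        if not matches:
            raise KeyError(
                f"no simple IE matching {numerator!r} in {role} {pathway}; "
                f"have {list(cell.simple_ies)}"
            )
        num = matches[0]
    pct = 100.0 * num / cell.total
    if not 0.0 <= pct <= 100.0:
        warnings.warn(
            f"proportion mediated {pct:.1f}% outside [0, 100] "
            f"({role} {pathway}): inconsistent mediation", stacklevel=2)
    return pct
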