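"""Loading and conditioning the published genome-scale reference model.

The engineered *P. putida* KT2440 reconstruction with the methyl-red to
actinorhodin pathway (iJN1462c) is distributed as supplementary material of
the original strain-design study; it is not bundled here. Drop the SBML
file at ``data/reference/iJN1462c.xml`` (relative to the repository root, or
pass an explicit path) and the reference-scale analyses become runnable.

Media follow the in-silico M9 minimal medium encoded in the file's exchange
bounds, with the carbon sources and oxygen toggled explicitly: MR uptake is
deliberately unconstrained at 1000 mmol gDW^-1 h^-1 and O2 is capped at
30 mmol gDW^-1 h^-1 (aerobic).
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

from .model import MetabolicModel, read_sbml

DEFAULT_LOCATIONS = (
    Path("data/reference/iJN1462c.xml"),
    Path(__file__).resolve().parents[2] / "data" / "reference" / "iJN1462c.xml",
)

MR_EXCHANGE = "EX_MR"
GLC_EXCHANGE = "EX_glc__D_e"
O2_EXCHANGE = "EX_o2_e"
MR_UPTAKE = 1000.0
O2_UPTAKE = 30.0

BIOMASS_REACTION = "BIOMASS_KT2440_WT3"
ACT_TRANSPORT = "ACTt"
MR_TRANSPORT = "MRt1"


class ReferenceModelMissing(FileNotFoundError):
    """The supplementary genome-scale SBML file is not available locally."""


def reference_model_path(path: str | Path | None = None) -> Path:
    if path is not None:
        p = Path(path)
        if p.exists():
            return p
        raise ReferenceModelMissing(f"reference model not found at {p}")
    for candidate in DEFAULT_LOCATIONS:
        if candidate.exists():
            return candidate
    raise ReferenceModelMissing(
        "the genome-scale reference model (iJN1462c, supplementary SBML) is "
        "not bundled with this package; place it at data/reference/iJN1462c.xml"
    )


def load_reference_model(path: str | Path | None = None) -> MetabolicModel:
    return read_sbml(reference_model_path(path))


def published_designs() -> dict:
    """The printed growth-coupled strain designs (knockouts, thresholds, and
    the published evaluation table) for the genome-scale reference model."""
    path = importlib.resources.files("azodesign.data") / "published_designs.json"
    return json.loads(path.read_text())


def set_reference_medium(
    model: MetabolicModel,
    carbon: str = "mr",
    glc_uptake: float | None = None,
    mr_uptake: float = MR_UPTAKE,
    o2_uptake: float = O2_UPTAKE,
) -> MetabolicModel:
    """Toggle the carbon sources of the as-distributed M9 bounds.

    Keeps every non-carbon exchange bound exactly as encoded in the file;
    ``glc_uptake=None`` likewise keeps the file's glucose bound when glucose
    is part of the requested medium.
    """
    if carbon not in ("mr", "glc", "glc_mr"):
        raise ValueError(f"unknown carbon configuration {carbon!r}")
    out = model.copy()

    def bound(rxn_id: str, lb: float) -> None:
        if rxn_id in out.reactions:
            out.reactions[rxn_id].lower_bound = lb

    mr_candidates = [r for r in (MR_EXCHANGE, "EX_mr_e") if r in out.reactions]
    if not mr_candidates:
        raise KeyError("no MR exchange reaction found in the reference model")
    mr_id = mr_candidates[0]
    bound(mr_id, -mr_uptake if carbon in ("mr", "glc_mr") else 0.0)
    if carbon in ("glc", "glc_mr"):
        if glc_uptake is not None:
            bound(GLC_EXCHANGE, -abs(glc_uptake))
        # else: keep the file's encoded M9 glucose bound
    else:
        bound(GLC_EXCHANGE, 0.0)
    bound(O2_EXCHANGE, -o2_uptake)
    return out
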