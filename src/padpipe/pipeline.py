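"""End-to-end convenience wrappers over the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .adv import ADVTemplate, quantify_session
from .core import Session
from .epochs import segment_session, select_agonists
from .modulation import ModulationProfile, compile_epoch_modulation


@dataclass
class SessionAnalysis:
    """Bundle of one session's segmentation, quantification and profile."""

    session: Session
    agonists: dict
    segmentations: dict
    outcomes: dict
    template: ADVTemplate
    measures: pd.DataFrame
    profile: ModulationProfile


def analyze_session(session: Session, target_torque: float = 1.0,
                    conduction_distance_m: Optional[float] = None,
                    min_stimuli: int = 50, min_rest: int = 20,
                    adv_id: object = 0) -> SessionAnalysis:
    """Segment, classify, quantify and compile one session."""
    agonists = select_agonists(session)
    segs, outcomes = segment_session(session, target_torque,
                                     agonists=agonists)
    template, measures = quantify_session(
        session, segs, outcomes,
        conduction_distance_m=conduction_distance_m,
        min_stimuli=min_stimuli, min_rest=min_rest)
    profile = compile_epoch_modulation(measures, adv_id=adv_id)
    return SessionAnalysis(session, agonists, segs, outcomes, template,
                           measures, profile)


def profiles_frame(analyses: list[SessionAnalysis]) -> pd.DataFrame:
    """Wide per-volley epoch-mean table for population statistics."""
    rows = []
    for a in analyses:
        for direction in ("flexion", "extension"):
            row = {"adv_id": a.profile.adv_id, "direction": direction}
            row.update(a.profile.epoch_row(direction))
            rows.append(row)
    return pd.DataFrame(rows)
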