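"""Nominate candidate DNA-binding residues.

Combines the ensemble contact ranking (top-k most DNA-contacting residues of
a domain) with evolutionary conservation: a residue is nominated when it sits
in the top-k by mean contact count AND its conservation score clears a
threshold tau.  Domains (e.g. individual homeodomains of a multi-domain
factor) are processed independently and the candidate lists concatenated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .contact_profiling import EnsembleContactTable, rank_residues
from .conservation import ConservationTrack
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NominationConfig:
    top_k: int = 4
    conservation_threshold: float = 0.5
    require_support: float = 0.0

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if not 0.0 <= self.conservation_threshold <= 1.0:
            raise ValidationError("conservation_threshold must lie in [0, 1]")


@dataclass
class CandidateResidue:
    residue: int
    mean_count: float
    support: float
    conservation: float
    domain: str = ""


@dataclass
class NominationResult:
    candidates: list[CandidateResidue]
    unscored: list[int] = field(default_factory=list)
    config: NominationConfig = NominationConfig()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "domain": c.domain,
                    "residue": c.residue,
                    "mean_count": c.mean_count,
                    "support": c.support,
                    "conservation": c.conservation,
                }
                for c in self.candidates
            ]
        )


def nominate(
    table: EnsembleContactTable,
    track: ConservationTrack,
    config: NominationConfig = NominationConfig(),
    domain: str = "",
) -> NominationResult:
    """Top-k contacted residues passing the conservation threshold.

    Candidates keep the contact ordering (descending mean count).  A top-k
    residue with no conservation score is reported as unscored and excluded,
    not raised.
    """
    ranked = rank_residues(table, k=config.top_k)
    candidates: list[CandidateResidue] = []
    unscored: list[int] = []
    for residue, mean_count, support in ranked:
        if support < config.require_support:
            continue
        score = track.scores.get(residue)
        if score is None:
            unscored.append(residue)
            logger.warning(
                "domain %s: top-%d residue %d has no conservation score; excluded",
                domain or "-", config.top_k, residue,
            )
            continue
        if score >= config.conservation_threshold:
            candidates.append(
                CandidateResidue(
                    residue=residue,
                    mean_count=mean_count,
                    support=support,
                    conservation=score,
                    domain=domain,
                )
            )
    return NominationResult(candidates=candidates, unscored=unscored, config=config)


def nominate_domains(
    domains: Mapping[str, tuple[EnsembleContactTable, ConservationTrack]],
    config: NominationConfig = NominationConfig(),
) -> NominationResult:
    """Run nomination per domain and concatenate the candidate lists."""
    all_candidates: list[CandidateResidue] = []
    all_unscored: list[int] = []
    for name in domains:
        table, track = domains[name]
        res = nominate(table, track, config=config, domain=name)
        all_candidates.extend(res.candidates)
        all_unscored.extend(res.unscored)
    return NominationResult(candidates=all_candidates, unscored=all_unscored, config=config)
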