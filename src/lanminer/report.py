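"""Whole-run mining report container shared by the summary and I/O layers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

if TYPE_CHECKING:
    from lanminer.bgc_classify import BgcCall
    from lanminer.cluster_annotate import CensusTable
    from lanminer.precursor_score import PrecursorCall


@dataclass
class MiningReport:
    """Per-run verdicts plus summary tallies.

    bgc_calls / precursor_calls are (bgc_id, call) pairs; every precursor
    call references an existing bgc_id.
    """

    bgc_calls: list[tuple[str, "BgcCall"]] = field(default_factory=list)
    precursor_calls: list[tuple[str, "PrecursorCall"]] = field(default_factory=list)
    census: "CensusTable | None" = None
    class_counts: dict[str, int] = field(default_factory=dict)
    precursor_class_counts: dict[str, int] = field(default_factory=dict)
    phylum_counts: dict[str, int] = field(default_factory=dict)
    gg_leader_fraction: float | None = None
    gc_pairs: list[tuple[str, float, float]] = field(default_factory=list)  # (bgc_id, bgc_gc, genome_gc)
    precursors_per_bgc_hist: dict[int, int] = field(default_factory=dict)
    config_hash: str = ""
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bgc_ids = {bid for bid, _ in self.bgc_calls}
        for bid, _ in self.precursor_calls:
            if bid not in bgc_ids:
                raise ValueError(f"precursor call references unknown BGC {bid}")
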