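"""Anchor-protein discovery and lanthipeptide class assignment (I-IV).

Class rules are applied independently, not as an if/else chain:
  I    - some neighborhood protein(s) hit BOTH dehydratase-N and
         dehydratase-C roles (possibly on different polypeptides: split
         dehydratases still classify);
  II   - some protein hits the class-II dehydratase domain role;
  III/IV - the anchor protein itself hits both the anchor and kinase roles,
         then the class III vs IV subfamily models are compared by E-value
         (III on a tie).
If several rules fire, precedence is I > II > III/IV with a multi-class
flag; if none fire the neighborhood is unclassified.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from lanminer.genome_io import GeneFeature, Neighborhood
from lanminer.hmm_profiles import HmmHit, ProfileHmm, hmm_search, load_hmm

ROLE_NAMES = ("anchor", "class1_n", "class1_c", "class2", "kinase", "class3", "class4")


@dataclass(frozen=True)
class ClassifierConfig:
    """The six role models driving class assignment."""

    anchor_hmm: ProfileHmm  # LanC-like cyclase role
    class1_n_hmm: ProfileHmm  # dehydratase N-terminal role
    class1_c_hmm: ProfileHmm  # dehydratase C-terminal role
    class2_hmm: ProfileHmm  # class-II dehydratase domain role
    kinase_hmm: ProfileHmm  # protein-kinase role
    class3_hmm: ProfileHmm  # class III cyclase subfamily
    class4_hmm: ProfileHmm  # class IV cyclase subfamily

    def role_of(self, hmm_name: str) -> str | None:
        for role in ROLE_NAMES:
            if getattr(self, f"{role}_hmm").name == hmm_name:
                return role
        return None

    @property
    def all_hmms(self) -> tuple[ProfileHmm, ...]:
        return (
            self.anchor_hmm,
            self.class1_n_hmm,
            self.class1_c_hmm,
            self.class2_hmm,
            self.kinase_hmm,
            self.class3_hmm,
            self.class4_hmm,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierConfig":
        """Load from a JSON object mapping role -> HMM file path."""
        data = json.loads(Path(path).read_text())
        kwargs = {}
        for role in ROLE_NAMES:
            kwargs[f"{role}_hmm"] = load_hmm(data[role])
        return cls(**kwargs)


@dataclass(frozen=True)
class BgcCall:
    neighborhood: Neighborhood
    lan_class: str  # I | II | III | IV | unclassified
    evidence: tuple[HmmHit, ...]
    contig_edge: bool
    multi_class_flag: bool
    class_genes: tuple[GeneFeature, ...] = ()


def find_lanc_proteins(
    proteins: Sequence[tuple[str, str]], config: ClassifierConfig
) -> list[HmmHit]:
    """Anchor-model hits at backend-default significance, best hit per protein."""
    if not proteins:
        return []
    hits = hmm_search([config.anchor_hmm], proteins, e_cutoff=None)
    best: dict[str, HmmHit] = {}
    for h in hits:
        cur = best.get(h.protein_id)
        if cur is None or h.evalue < cur.evalue:
            best[h.protein_id] = h
    return sorted(best.values(), key=lambda h: (h.evalue, h.protein_id))


def _genes_with_role(nbhd: Neighborhood, hits_by_role: dict[str, dict[str, HmmHit]], role: str) -> list[GeneFeature]:
    ids = hits_by_role.get(role, {})
    return [g for g in nbhd.genes if g.protein_id in ids or g.locus_id in ids]


def assign_class(
    nbhd: Neighborhood, hits: Sequence[HmmHit], config: ClassifierConfig
) -> BgcCall:
    """Assign a neighborhood to lanthipeptide class I, II, III, IV or
    unclassified from HMM hits over its proteins.

    `hits` must cover the neighborhood's proteins searched against all
    config models; the anchor protein must itself carry an anchor-model
    hit (anything else is a pipeline bug).
    """
    anchor_id = nbhd.anchor.protein_id or nbhd.anchor.locus_id
    hits_by_role: dict[str, dict[str, HmmHit]] = {}
    for h in hits:
        role = config.role_of(h.hmm_name)
        if role is None:
            continue
        bucket = hits_by_role.setdefault(role, {})
        cur = bucket.get(h.protein_id)
        if cur is None or h.evalue < cur.evalue:
            bucket[h.protein_id] = h
    if anchor_id not in hits_by_role.get("anchor", {}):
        raise ValueError(f"anchor protein {anchor_id} has no anchor-model hit: pipeline bug")

    fired: list[str] = []
    evidence: list[HmmHit] = [hits_by_role["anchor"][anchor_id]]
    class_genes: tuple[GeneFeature, ...] = ()

    c1n = hits_by_role.get("class1_n", {})
    c1c = hits_by_role.get("class1_c", {})
    if c1n and c1c:
        fired.append("I")
    c2 = hits_by_role.get("class2", {})
    if c2:
        fired.append("II")
    kinase_on_anchor = anchor_id in hits_by_role.get("kinase", {})
    sub_class: str | None = None
    if kinase_on_anchor:
        e3 = hits_by_role.get("class3", {}).get(anchor_id)
        e4 = hits_by_role.get("class4", {}).get(anchor_id)
        ev3 = e3.evalue if e3 else math.inf
        ev4 = e4.evalue if e4 else math.inf
        sub_class = "III" if ev3 <= ev4 else "IV"  # tie goes to III
        fired.append(sub_class)

    if not fired:
        lan_class = "unclassified"
    else:
        lan_class = fired[0]  # precedence I > II > III/IV by construction order

    if lan_class == "I":
        evidence += sorted(set(c1n.values()) | set(c1c.values()), key=lambda h: h.evalue)
        class_genes = tuple(
            dict.fromkeys(_genes_with_role(nbhd, hits_by_role, "class1_n") + _genes_with_role(nbhd, hits_by_role, "class1_c"))
        )
    elif lan_class == "II":
        evidence += sorted(c2.values(), key=lambda h: h.evalue)
        class_genes = tuple(_genes_with_role(nbhd, hits_by_role, "class2"))
    elif lan_class in ("III", "IV"):
        evidence.append(hits_by_role["kinase"][anchor_id])
        for role in ("class3", "class4"):
            h = hits_by_role.get(role, {}).get(anchor_id)
            if h:
                evidence.append(h)
        class_genes = (nbhd.anchor,)

    return BgcCall(
        neighborhood=nbhd,
        lan_class=lan_class,
        evidence=tuple(evidence),
        contig_edge=nbhd.contig_edge,
        multi_class_flag=len(fired) > 1,
        class_genes=class_genes,
    )
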