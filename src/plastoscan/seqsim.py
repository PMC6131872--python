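"""Synthetic plastome data: alignments, chimeras, indels, and read libraries.

The generative model for phylogenetic conflict is a two-tree chimera: the
bulk of a ~130 kb alignment evolves under GTR+Gamma+I on a backbone species
topology, while one contiguous segment (default columns 31,000-46,000,
~15 kb) evolves on an alternative topology in which *Cupressus* is sister
to *Juniperus* instead of to the CaHX clade.  This is the operational form
of an ancient introgression: distinct plastid haplotypes established by
hybridization or incomplete lineage sorting, a transiently heteroplasmic
individual, and recombination splicing a foreign segment into an otherwise
native plastome.  Indel hotspots inside the segment mimic the high indel
rate of the *ycf1*/*ycf2* genes.

Genome-isomer libraries emulate a plastome present as a mixture of two
inverted-repeat arrangements ("A"/"B") at a given stoichiometry, from which
error-free paired reads are drawn.

All simulators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .substmodel import GTRGIParams, build_rate_matrix, gamma_rates, transition_probs_many
from .treelik import PhyloTree, parse_newick
from .structscan import ArrangementSpec, revcomp

__all__ = [
    "default_model",
    "backbone_topology",
    "alternative_topology",
    "ChimeraSpec",
    "simulate_alignment",
    "simulate_chimera",
    "inject_indels",
    "simulate_arrangement_spec",
    "simulate_ir_library",
    "write_fastq",
]

_BASES = "ACGT"


def default_model() -> GTRGIParams:
    """Desk-scale plastome-like model: moderately AT-rich, alpha=0.5, p_inv=0.3."""
    return GTRGIParams(
        exchangeabilities=(1.1, 3.0, 0.8, 0.9, 3.2, 1.0),
        freqs=(0.30, 0.20, 0.20, 0.30),
        alpha=0.5,
        p_inv=0.3,
        n_cat=4,
    )


# Default 8-taxon leaf set: two Juniperus, two Cupressus, one each of
# Callitropsis / Hesperocyparis / Xanthocyparis, one outgroup.  Branch
# lengths of order 0.01-0.05: divergence at this taxonomic depth is shallow.
_BACKBONE_8 = (
    "(Outgroup:0.05,(Juniperus_1:0.02,Juniperus_2:0.02):0.03,"
    "((Cupressus_1:0.02,Cupressus_2:0.02):0.02,"
    "((Callitropsis:0.015,Hesperocyparis:0.015):0.01,Xanthocyparis:0.02)"
    ":0.015):0.01);"
)
_ALTERNATIVE_8 = (
    "(Outgroup:0.05,((Juniperus_1:0.02,Juniperus_2:0.02):0.02,"
    "(Cupressus_1:0.02,Cupressus_2:0.02):0.02):0.015,"
    "((Callitropsis:0.015,Hesperocyparis:0.015):0.01,Xanthocyparis:0.02)"
    ":0.02);"
)

# 21-taxon preset mirroring the published sampling: 6 Juniperus, 6
# Cupressus, 5 Hesperocyparis, Callitropsis, Xanthocyparis, 2 outgroups.
def _clade(names, tip=0.015, stem=0.01):
    s = names[0] + f":{tip}"
    for n in names[1:]:
        s = f"({s},{n}:{tip}):{stem}"
    return s


def _topology_21(cupressus_with_juniperus: bool) -> str:
    jun = _clade([f"Juniperus_{i}" for i in range(1, 7)])
    cup = _clade([f"Cupressus_{i}" for i in range(1, 7)])
    hes = _clade([f"Hesperocyparis_{i}" for i in range(1, 6)])
    cahx = f"(({hes},Callitropsis:0.015):0.01,Xanthocyparis:0.02):0.01"
    if cupressus_with_juniperus:
        core = f"(({jun},{cup}):0.015,{cahx}):0.02"
    else:
        core = f"({jun}:0.015,({cup},{cahx}):0.01):0.02"
    return f"(Outgroup_1:0.05,Outgroup_2:0.05,{core});"


def backbone_topology(n_taxa: int = 8) -> PhyloTree:
    """Species topology: Cupressus sister to the CaHX clade, Juniperus outside."""
    if n_taxa == 8:
        return parse_newick(_BACKBONE_8)
    if n_taxa == 21:
        return parse_newick(_topology_21(False))
    raise ValueError("presets exist for 8 and 21 taxa")


def alternative_topology(n_taxa: int = 8) -> PhyloTree:
    """Conflicting topology: Cupressus sister to Juniperus."""
    if n_taxa == 8:
        return parse_newick(_ALTERNATIVE_8)
    if n_taxa == 21:
        return parse_newick(_topology_21(True))
    raise ValueError("presets exist for 8 and 21 taxa")


def simulate_alignment(
    tree: PhyloTree,
    model: GTRGIParams,
    length: int,
    seed: int,
    rng: np.random.Generator | None = None,
) -> Alignment:
    """Evolve ``length`` sites on ``tree`` under GTR+Gamma+I.

    Root states are drawn from the stationary distribution; each site draws
    one rate class (shared across the whole tree) and states evolve down
    every branch via the transition probabilities.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    rm = build_rate_matrix(model)
    cats = gamma_rates(model.alpha, model.n_cat, model.p_inv)
    ncat = len(cats.rates)
    cat_idx = rng.choice(ncat, size=length, p=cats.weights)
    states = {tree.root: rng.choice(4, size=length, p=rm.freqs)}
    for node in reversed(tree.postorder()):  # preorder
        for child in tree.nodes[node].children:
            t = max(tree.nodes[child].length, 0.0)
            P = transition_probs_many(rm, t * cats.rates)  # (ncat, 4, 4)
            cum = np.cumsum(P, axis=2)
            cum[:, :, 3] = 1.0
            thresh = cum[cat_idx, states[node]]            # (L, 4)
            u = rng.random(length)
            states[child] = (u[:, None] > thresh).sum(axis=1).astype(np.uint8)
    taxa = tree.leaf_labels
    data = np.stack([states[i] for i in tree.leaf_indices])
    return Alignment(list(taxa), data)


@dataclass
class ChimeraSpec:
    """Conditions for a chimeric (introgressed-segment) alignment.

    ``segment`` is 1-based inclusive on the simulated alignment.  Indel
    hotspots (inside the segment) use ``indel_rate * hotspot_multiplier``.
    """

    backbone: PhyloTree = field(default_factory=backbone_topology)
    alternative: PhyloTree = field(default_factory=alternative_topology)
    segment: tuple[int, int] = (31000, 46000)
    length: int = 130000
    model: GTRGIParams = field(default_factory=default_model)
    indel_rate: float = 0.0
    indel_mean_length: float = 4.0
    hotspot_multiplier: float = 4.0
    seed: int = 0

    def __post_init__(self):
        s, e = self.segment
        if not (s >= 1 and e <= self.length and e >= s - 1):
            raise ValueError("segment must lie within [1, length]")
        if set(self.backbone.leaf_labels) != set(self.alternative.leaf_labels):
            raise ValueError("topologies must share one leaf set")

    def truth(self) -> dict:
        return {
            "segment": list(self.segment),
            "length": self.length,
            "seed": self.seed,
            "indel_rate": self.indel_rate,
            "hotspot_multiplier": self.hotspot_multiplier,
            "model": self.model.to_config(),
            "backbone": self.backbone.to_newick(),
            "alternative": self.alternative.to_newick(),
        }

    def truth_bed(self) -> str:
        s, e = self.segment
        return f"chimera\t{s - 1}\t{e}\talternative_topology_segment\n"


def simulate_chimera(spec: ChimeraSpec) -> tuple[Alignment, dict]:
    """Backbone-topology alignment with one alternative-topology segment."""
    rng = np.random.default_rng(spec.seed)
    aln = simulate_alignment(spec.backbone, spec.model, spec.length, 0, rng=rng)
    s, e = spec.segment
    if e >= s:
        seg = simulate_alignment(spec.alternative, spec.model, e - s + 1, 0, rng=rng)
        order = [seg.taxa.index(t) for t in aln.taxa]
        aln.data[:, s - 1 : e] = seg.data[order]
    if spec.indel_rate > 0:
        aln = inject_indels(
            aln,
            rate=spec.indel_rate,
            mean_length=spec.indel_mean_length,
            hotspots=[((s, e), spec.hotspot_multiplier)],
            seed=None,
            rng=rng,
        )
    return aln, spec.truth()


def inject_indels(
    aln: Alignment,
    rate: float,
    mean_length: float = 4.0,
    hotspots: list | None = None,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> Alignment:
    """Overlay gap runs on an alignment (deletions as gap characters).

    ``rate`` is the per-taxon, per-column probability that a gap run starts
    there; run lengths are geometric with the given mean; ``hotspots`` is a
    list of ``((start, end), multiplier)`` with 1-based inclusive column
    intervals whose start rate is multiplied.  Row lengths are preserved.
    """
    if not 0.0 <= rate <= 0.5:
        raise ValueError("indel rate must be in [0, 0.5]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if rate == 0.0:
        return Alignment(list(aln.taxa), aln.data.copy(), coords=aln.coords)
    n, L = aln.data.shape
    col_rate = np.full(L, rate)
    for (s, e), mult in hotspots or []:
        col_rate[s - 1 : e] = rate * mult
    data = aln.data.copy()
    from .alignment import GAP_CODE

    p_geom = 1.0 / max(mean_length, 1.0)
    starts = rng.random((n, L)) < col_rate[None, :]
    lens = rng.geometric(p_geom, size=(n, L))
    for i, j in zip(*np.nonzero(starts)):
        data[i, j : j + lens[i, j]] = GAP_CODE
    return Alignment(list(aln.taxa), data, coords=aln.coords)


# ---------------------------------------------------------------------------
# IR-isomer read libraries
# ---------------------------------------------------------------------------

def simulate_arrangement_spec(
    seed: int = 0,
    length: int = 12000,
    ir_length: int = 260,
    ir1_start: int = 3000,
    segment_length: int = 4000,
) -> ArrangementSpec:
    """Random genome with a planted inverted repeat pair (synthetic stand-in
    for a Cupressaceae plastome with its trnQ-IR)."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(list(_BASES), size=length)
    s1 = ir1_start
    e1 = s1 + ir_length - 1
    s2 = e1 + segment_length + 1
    e2 = s2 + ir_length - 1
    if e2 > length:
        raise ValueError("genome too short for requested IR layout")
    ir = "".join(rng.choice(list(_BASES), size=ir_length))
    genome = "".join(seq)
    genome = genome[: s1 - 1] + ir + genome[e1:]
    genome = genome[: s2 - 1] + revcomp(ir) + genome[e2:]
    return ArrangementSpec(genome, (s1, e1), (s2, e2))


def simulate_ir_library(
    spec: ArrangementSpec,
    fraction_B: float,
    n_pairs: int,
    read_len: int = 150,
    insert_mean: float = 400.0,
    insert_sd: float = 50.0,
    seed: int = 0,
    span_only: bool = False,
    min_flank: int = 50,
) -> tuple[list, dict]:
    """Error-free paired reads from a mixture of the two IR arrangements.

    Each pair is drawn from arrangement B with probability ``fraction_B``,
    else A.  By default fragment starts are uniform over the genome; with
    ``span_only=True`` fragments are conditioned to span one IR copy with at
    least ``min_flank`` bases on each side (a spanning-enriched library for
    desk-scale classifier studies).  Returns ``(pairs, truth)`` where pairs
    are ``(read_id, mate1, mate2)`` and truth maps read id to "A"/"B".
    """
    if not 0.0 <= fraction_B <= 1.0:
        raise ValueError("fraction_B must be in [0, 1]")
    if insert_mean < read_len:
        raise ValueError("insert size must be at least the read length")
    rng = np.random.default_rng(seed)
    refs = {"A": spec.seq_A, "B": spec.seq_B}
    G = len(spec.genome)
    ir0 = spec.ir_intervals0()
    min_insert = max(read_len, spec.ir_length + 2 * min_flank)
    pairs, truth = [], {}
    for k in range(n_pairs):
        label = "B" if rng.random() < fraction_B else "A"
        ref = refs[label]
        insert = int(round(rng.normal(insert_mean, insert_sd)))
        if span_only:
            insert = max(insert, min_insert + 1)
            s, e = ir0[rng.integers(0, len(ir0))]
            lo = max(0, e + min_flank - insert)
            hi = min(G - insert, s - min_flank)
            if hi < lo:
                raise ValueError("insert too short to span the IR with flanks")
            start = int(rng.integers(lo, hi + 1))
        else:
            insert = max(insert, read_len)
            insert = min(insert, G)
            start = int(rng.integers(0, G - insert + 1))
        frag = ref[start : start + insert]
        m1 = frag[:read_len]
        m2 = revcomp(frag[-read_len:])
        rid = f"pair_{k:06d}"
        pairs.append((rid, m1, m2))
        truth[rid] = label
    return pairs, truth


def write_fastq(pairs, path1, path2) -> None:
    """Write mates to two FASTQ files (quality 'I' for every base)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rid, m1, m2 in pairs:
            f1.write(f"@{rid}/1\n{m1}\n+\n{'I' * len(m1)}\n")
            f2.write(f"@{rid}/2\n{m2}\n+\n{'I' * len(m2)}\n")


def write_truth_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
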