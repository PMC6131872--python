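"""End-to-end conflict analysis: fit, scan, call, split, test.

Ties the stages together the way the full analysis runs on a plastome
alignment: fit both candidate topologies, form the per-site Delta-lnL
profile, scan it in sliding windows, call conflict regions, split the
alignment at the called regions, and re-test both topologies on each
partition with the SH (and optionally AU) test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .treelik import PhyloTree, fit_on_topology
from .conflictscan import (
    delta_profile,
    window_scan,
    call_regions,
    split_alignment,
    WindowScan,
    ConflictRegion,
)
from .topotest import TopologySet, sh_test, au_test, TestResult

__all__ = ["ConflictReport", "run_conflict_pipeline", "partition_tests"]


@dataclass
class PartitionResult:
    name: str
    n_columns: int
    preferred: str
    sh: list[TestResult]
    au: list[TestResult] | None = None


@dataclass
class ConflictReport:
    fits: dict
    scan: WindowScan
    regions: list[ConflictRegion]
    partitions: list[PartitionResult] = field(default_factory=list)
    seed: int = 0


def partition_tests(
    aln: Alignment,
    topologies: list[PhyloTree],
    ids: list[str],
    name: str = "partition",
    n_sh: int = 10000,
    seed: int = 0,
    free: tuple = ("brlen", "alpha", "p_inv"),
    with_au: bool = False,
    model0s: list | None = None,
    fit_kwargs: dict | None = None,
) -> PartitionResult:
    """Refit every candidate topology on one partition and run SH (and AU).

    ``model0s`` supplies per-topology starting models (e.g. the
    whole-alignment fits) to warm-start the partition refits.
    """
    if model0s is None:
        model0s = [None] * len(topologies)
    fk = fit_kwargs or {}
    fits = [
        fit_on_topology(aln, t, topology_id=i, free=free, model0=m0, **fk)
        for t, i, m0 in zip(topologies, ids, model0s)
    ]
    ts = TopologySet([f.profile for f in fits])
    sh = sh_test(ts, n=n_sh, seed=seed)
    au = au_test(ts, seed=seed) if with_au else None
    preferred = ids[int(np.argmax([f.lnl for f in fits]))]
    return PartitionResult(
        name=name, n_columns=aln.n_columns, preferred=preferred, sh=sh, au=au
    )


def run_conflict_pipeline(
    aln: Alignment,
    topology1: PhyloTree,
    topology2: PhyloTree,
    ids: tuple = ("T1", "T2"),
    window_size: int = 5000,
    step: int = 100,
    min_run: int = 10,
    mad_k: float = 3.0,
    n_sh: int = 10000,
    seed: int = 0,
    free: tuple = ("brlen", "alpha", "p_inv"),
    with_au: bool = False,
    fit_kwargs: dict | None = None,
) -> ConflictReport:
    """Whole-alignment scan plus per-partition topology tests.

    The Delta-lnL sign convention is lnL(topology1) - lnL(topology2):
    positive windows favor ``topology1``.  ``fit_kwargs`` (e.g.
    ``max_cycles``, ``tol``) are forwarded to every fit.
    """
    fk = fit_kwargs or {}
    fit1 = fit_on_topology(aln, topology1, topology_id=ids[0], free=free, **fk)
    fit2 = fit_on_topology(aln, topology2, topology_id=ids[1], free=free, **fk)
    delta = delta_profile(fit1.profile, fit2.profile)
    scan = window_scan(delta, window_size=window_size, step=step)
    regions = call_regions(scan, min_run=min_run, mad_k=mad_k, aln=aln)
    report = ConflictReport(
        fits={ids[0]: fit1, ids[1]: fit2}, scan=scan, regions=regions, seed=seed
    )
    if regions:
        inside, outside = split_alignment(aln, regions)
        for name, sub in (("conflict_region", inside), ("remainder", outside)):
            report.partitions.append(
                partition_tests(
                    sub,
                    [topology1, topology2],
                    list(ids),
                    name=name,
                    n_sh=n_sh,
                    seed=seed,
                    free=free,
                    with_au=with_au,
                    model0s=[fit1.params, fit2.params],
                    fit_kwargs=fit_kwargs,
                )
            )
    return report
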