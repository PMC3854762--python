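"""End-to-end desk-scale studies tying the pipeline stages together.

These orchestrators are what the command line, the examples and the
acceptance script call: synthetic decoy studies (partner recovery with
experimental and predicted interfaces), planted environment-competition
studies, and a full docking study on toy proteins with and without the
conformational-space restriction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .benchmark import Benchmark
from .config import Config, DEFAULTS
from .docking import DecoySet, dock_pair, tube_filter
from .energy import EnergyParams
from .environment import (IRSignature, false_positives_at, rank_recovery_table,
                          sample_environments, signature)
from .evaluation import GoldStandard, metrics_at, roc_auc
from .propensity import (combine, fir_predicted, interaction_propensity,
                         jet_frequency, nip_interface, normalize_nip)
from .reduced import InterfaceSpec, ReducedProtein, ResidueId
from .scoring import nii_from_decoys, predicted_partner
from .synth import (DecoyCollection, SyntheticDecoyConfig, ToySpec,
                    complementary_params, make_decoy_collection,
                    make_synthetic_jet, make_toy_protein, plant_patch_types)

log = logging.getLogger(__name__)


def combined_scores(coll_decoys: Mapping[tuple[str, str], DecoySet],
                    surfaces: Mapping[str, frozenset[ResidueId]],
                    jet_runs: Mapping[str, list[frozenset[ResidueId]]],
                    weights: Mapping[str, tuple[float, float]] | None = None,
                    config: Config = DEFAULTS
                    ) -> tuple[dict[str, dict[ResidueId, float]],
                               dict[str, InterfaceSpec]]:
    """JET+NIP combined residue scores and NIP-predicted interfaces.

    ``weights`` optionally overrides the (a, b) profile per protein
    (e.g. the lowered-JET profile for antibody/antigen proteins).
    """
    scores: dict[str, dict[ResidueId, float]] = {}
    nip_sites: dict[str, InterfaceSpec] = {}
    for pid, surface in surfaces.items():
        sets = [ds for pair, ds in coll_decoys.items() if pid in pair]
        ip = interaction_propensity(pid, sets, surface, config=config)
        nip = normalize_nip(ip, surface)
        nip_sites[pid] = nip_interface(nip, pid, config=config)
        jet = jet_frequency(jet_runs[pid], surface)
        a, b = weights.get(pid, (config.combine_a, config.combine_b)) \
            if weights else (config.combine_a, config.combine_b)
        scores[pid] = combine(nip, jet, a, b, config=config)
    return scores, nip_sites


def nii_predicted(decoy_sets: Mapping[tuple[str, str], DecoySet],
                  scores: Mapping[str, dict[ResidueId, float]],
                  config: Config = DEFAULTS) -> pd.DataFrame:
    """NII matrix scored with combined residue scores instead of
    experimental interfaces."""
    def factory(rid: str, lid: str):
        sr, sl = scores[rid], scores[lid]
        return lambda c: fir_predicted(c, sr, sl, config=config).fir_overall

    return nii_from_decoys(decoy_sets, fir_factory=factory, config=config)


@dataclass
class PartnerStudy:
    collection: DecoyCollection
    nii_experimental: pd.DataFrame
    nii_predicted: pd.DataFrame
    auc_experimental: float
    auc_predicted: float
    metrics_experimental: dict
    metrics_predicted: dict
    recovery: dict[str, float]   # fraction of proteins whose predicted partner is native


def _partner_recovery(nii: pd.DataFrame, gold: GoldStandard) -> float:
    partner = {}
    for p in gold.native_pairs:
        a, b = sorted(p)
        partner[a], partner[b] = b, a
    hits = sum(1 for p in nii.index if p in partner
               and predicted_partner(nii, p) == partner[p])
    return hits / len(partner)


def run_partner_study(n_complexes: int = 4, n_conformations: int = 400,
                      p_signal: float = 0.9, sigma: float = 2.0,
                      jet_enrichment: float = 0.9, seed: int = 0,
                      config: Config = DEFAULTS) -> PartnerStudy:
    """Synthetic planted-decoy partner-identification study.

    Builds a decoy collection over all ordered pairs, scores it both
    with the planted (reference) interfaces and with JET+NIP predicted
    scores, and evaluates AUC, threshold metrics and predicted-partner
    recovery.
    """
    coll = make_decoy_collection(SyntheticDecoyConfig(
        n_complexes=n_complexes, n_conformations=n_conformations,
        p_signal=p_signal, sigma=sigma, seed=seed))
    nii_exp = nii_from_decoys(coll.decoy_sets, references=coll.patches,
                              config=config)
    jet_runs = make_synthetic_jet(coll.patches, coll.surfaces,
                                  enrichment=jet_enrichment, seed=seed + 1)
    scores, _ = combined_scores(coll.decoy_sets, coll.surfaces, jet_runs,
                                config=config)
    nii_pred = nii_predicted(coll.decoy_sets, scores, config=config)
    return PartnerStudy(
        coll, nii_exp, nii_pred,
        roc_auc(nii_exp, coll.gold), roc_auc(nii_pred, coll.gold),
        metrics_at(nii_exp, coll.gold, config.nii_threshold_experimental),
        metrics_at(nii_pred, coll.gold, config.nii_threshold_predicted),
        {"experimental": _partner_recovery(nii_exp, coll.gold),
         "predicted": _partner_recovery(nii_pred, coll.gold)})


@dataclass
class EnvironmentStudy:
    nii: pd.DataFrame
    benchmark: Benchmark
    signatures: list[IRSignature]
    target: tuple[str, str]
    mean_ir_native: float
    sd_ir_native: float
    environment_sizes: list[int]
    false_positives: int
    recovery_table: pd.DataFrame


def run_environment_study(n_complexes: int = 30, seed: int = 0,
                          n_sets: int | None = None,
                          n_env_complexes: int | None = None,
                          promiscuous: str | None = None,
                          inert: str | None = None,
                          noise: float = 0.05,
                          config: Config = DEFAULTS) -> EnvironmentStudy:
    """Competition analysis on a planted NII matrix.

    The matrix plants native pairs high, background pairs low, an
    optional promiscuous protein high against everyone and an optional
    inert protein low against everyone; environments are sampled around
    the first native complex.
    """
    from .synth import make_planted_nii

    nii, bench = make_planted_nii(n_complexes, noise=noise, seed=seed,
                                  promiscuous=promiscuous, inert=inert)
    target = bench.pairs[0]
    envs = sample_environments(bench.pairs, target, n_sets=n_sets,
                               n_complexes=n_env_complexes, seed=seed,
                               config=config)
    sizes = [len(e.proteins) for e in envs]
    query = target[0]
    candidates = [p for p in bench.proteins if p != query]
    sigs = signature(query, candidates, nii, bench.pairs, seed=seed,
                     n_sets=min(20, n_sets or config.env_n_sets),
                     n_complexes=n_env_complexes, config=config)
    native_sig = next(s for s in sigs if s.candidate == target[1])
    fps = false_positives_at(query, sigs, target[1], config=config)
    table = rank_recovery_table(nii, bench.pairs)
    return EnvironmentStudy(nii, bench, sigs, target, native_sig.mean_ir,
                            native_sig.sd_ir, sizes, fps, table)


@dataclass
class DockingStudy:
    benchmark: Benchmark
    proteins: dict[str, ReducedProtein]
    params: EnergyParams
    decoy_sets: dict[tuple[str, str], DecoySet]
    decoy_sets_restricted: dict[tuple[str, str], DecoySet]
    references: dict[str, InterfaceSpec]
    nii_experimental: pd.DataFrame
    nii_restricted: pd.DataFrame
    nii_predicted: pd.DataFrame
    auc_experimental: float
    auc_restricted: float
    auc_predicted: float
    retained_fraction: float
    gold: GoldStandard = field(default=None)


def build_toy_benchmark(n_complexes: int = 4, n_residues: int = 12,
                        patch_size: int = 4, seed: int = 0
                        ) -> tuple[Benchmark, dict[str, ReducedProtein],
                                   dict[str, InterfaceSpec], EnergyParams]:
    """Toy proteins for a synthetic benchmark with complementary patches.

    Each complex gets a receptor and a ligand rod whose planted patches
    carry complex-specific LJ types that attract each other strongly,
    engineering one complementary patch pair per native complex.
    """
    from .benchmark import synthetic_benchmark

    import zlib

    bench = synthetic_benchmark(n_complexes)
    proteins: dict[str, ReducedProtein] = {}
    refs: dict[str, InterfaceSpec] = {}
    patch_pairs = []
    lo = (n_residues - patch_size) // 2
    for k, (rec, lig) in enumerate(bench.pairs):
        for pid, tname in ((rec, f"PATCH{k}R"), (lig, f"PATCH{k}L")):
            spec = ToySpec(n_residues=n_residues, patch=(lo, lo + patch_size),
                           seed=seed * 1000 + zlib.crc32(pid.encode()) % 997,
                           protein_id=pid)
            _, reduced = make_toy_protein(spec)
            reduced = plant_patch_types(reduced, spec.patch_residues, tname)
            proteins[pid] = reduced
            refs[pid] = InterfaceSpec(pid, spec.patch_residues)
        patch_pairs.append((f"PATCH{k}R", f"PATCH{k}L"))
    return bench, proteins, refs, complementary_params(patch_pairs)


def run_docking_study(n_complexes: int = 3, n_residues: int = 10,
                      patch_size: int = 4, n_directions: int = 16,
                      n_orientations: int = 2, seed: int = 0,
                      tube_radius: float = 6.0,
                      config: Config = DEFAULTS) -> DockingStudy:
    """Full-engine cross-docking of toy proteins, unrestricted and
    tube-restricted, in experimental and JET+NIP scoring modes.

    The restricted decoy sets reuse the unrestricted minimisations:
    restriction filters start axes, and minimisations are independent
    per start, so dropping conformations whose start fails the tube test
    is identical to restricting before docking.
    """
    bench, proteins, refs, params = build_toy_benchmark(
        n_complexes, n_residues, patch_size, seed)
    ids = bench.proteins
    decoys: dict[tuple[str, str], DecoySet] = {}
    for rec in ids:
        for lig in ids:
            if rec == lig:
                continue
            decoys[(rec, lig)] = dock_pair(
                proteins[rec], proteins[lig], params, config=config,
                seed=seed, n_directions=n_directions,
                n_orientations=n_orientations)
    # tube restriction, reusing the unrestricted minimisations
    restricted: dict[tuple[str, str], DecoySet] = {}
    kept = total = 0
    for (rec, lig), ds in decoys.items():
        keep = [c for c in ds.conformations
                if tube_filter(proteins[rec], refs[rec], c.start,
                               radius=tube_radius, config=config)]
        total += len(ds)
        kept += len(keep)
        if keep:
            meta = dict(ds.metadata, restricted=True,
                        n_retained_starts=len(keep))
            restricted[(rec, lig)] = DecoySet(rec, lig, keep, meta)
    gold = bench.gold_standard()
    nii_exp = nii_from_decoys(decoys, references=refs, config=config)
    nii_res = nii_from_decoys(restricted, references=refs, config=config)
    jet_runs = make_synthetic_jet(refs, {p: frozenset(proteins[p].residue_ids)
                                         for p in ids}, seed=seed + 1)
    scores, _ = combined_scores(decoys,
                                {p: frozenset(proteins[p].residue_ids)
                                 for p in ids}, jet_runs, config=config)
    nii_pred = nii_predicted(decoys, scores, config=config)
    return DockingStudy(bench, proteins, params, decoys, restricted, refs,
                        nii_exp, nii_res, nii_pred,
                        roc_auc(nii_exp, gold), roc_auc(nii_res, gold),
                        roc_auc(nii_pred, gold),
                        kept / total if total else 0.0, gold=gold)
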