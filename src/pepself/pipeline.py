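"""End-to-end synthetic analysis: one config in, a directory of TSVs out.

Wires the stages together the way the full study runs: generate (or load)
proteomes, predict per-allele presented sets, enumerate exact and
degenerate self/nonself overlaps, scan peptide lengths with shuffled
controls, compute the cross-reactivity footprint and positional entropy,
and test the immunogenicity association on labels with a planted effect.
All randomness derives from one root seed; the manifest records the config
hash so a rerun is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__, synthetic
from .crossreactivity import average_footprint
from .immunogenicity import association_report, classify_labels, overlap_table
from .overlap import SelfIndex, length_scan, overlap_fraction
from .peptidome import extract_kmers
from .presentation import ThresholdSpec, presented_set
from .recognition import RecognitionModel, build_similarity_rule
from .stats import additional_anchor_assessment, position_entropy

#: stage name -> offset added to the root seed (documented derivation)
SEED_OFFSETS = {
    "proteomes": 0,
    "allele": 1,
    "matrix": 2,
    "labels": 3,
    "shuffle": 4,
}


def derive_seed(root_seed: int, stage: str) -> int:
    if stage not in SEED_OFFSETS:
        raise KeyError(f"unknown stage {stage!r}")
    return (root_seed * 1000 + SEED_OFFSETS[stage]) % (2**31 - 1)


def _config_hash(cfg: Mapping[str, str]) -> str:
    canon = json.dumps({k: str(v) for k, v in sorted(cfg.items())}, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def run_pipeline(cfg: Mapping[str, str], outdir: str | Path) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 1))
    n_self = int(cfg.get("n_self_proteins", 50))
    n_species = int(cfg.get("n_species", 4))
    if n_species < 1:
        raise ValueError("at least one nonself proteome is required")
    rate = float(cfg.get("shared_kmer_rate", 0.05))
    allele = cfg.get("allele", "SYN-A01")
    anchor_strength = float(cfg.get("anchor_strength", 2.0))
    mean_similar = float(cfg.get("mean_similar_partners", 1.6))
    mode = cfg.get("threshold_mode", "scaled")
    target = float(cfg.get("target_specificity", 0.023))

    provenance = f"# pepself {__version__} | seed={seed}\n"

    def write(df: pd.DataFrame, name: str) -> None:
        with open(outdir / name, "w") as fh:
            fh.write(provenance)
            df.to_csv(fh, sep="\t", index=False)

    # 1. inputs
    data = synthetic.make_proteomes(
        n_self_proteins=n_self, n_species=n_species, shared_kmer_rate=rate,
        seed=derive_seed(seed, "proteomes"),
    )
    binding = synthetic.make_allele(
        name=allele, anchor_strength=anchor_strength, seed=derive_seed(seed, "allele")
    )
    matrix = synthetic.make_similarity_matrix(
        mean_similar, seed=derive_seed(seed, "matrix")
    )
    rule = build_similarity_rule(matrix, "abs_covariance_gt", 0.05)

    # 2. presented sets
    self_kmers = extract_kmers(data.self_proteome, 9)
    spec = ThresholdSpec(mode=mode, target_specificity=target)
    self_presented = presented_set(
        binding, self_kmers.peptides, spec, species_id="self", kingdom="self"
    )
    nonself_presented = []
    for prot in data.nonself_proteomes:
        km = extract_kmers(prot, 9)
        pres = presented_set(
            binding, km.peptides, spec, self_peptides=self_kmers.peptides,
            species_id=prot.species_id, kingdom=prot.kingdom,
        )
        km.peptides = pres.peptides
        nonself_presented.append(km)

    # 3. overlaps per model (Fig 2 analogue)
    models = {
        "complete": RecognitionModel.complete(),
        "middle": RecognitionModel.middle(),
        "nonanchor": RecognitionModel.nonanchor(),
        "degenerate": RecognitionModel.degenerate(rule),
    }
    frames = []
    summary_rows = []
    for name, model in models.items():
        result = overlap_fraction(nonself_presented, self_presented.peptides,
                                  model, allele=allele)
        df = result.to_frame().assign(model=name)
        frames.append(df)
        summary_rows.append({"model": name, "kingdom_average": result.kingdom_average})
    write(pd.concat(frames, ignore_index=True), "overlap_per_species.tsv")
    write(pd.DataFrame(summary_rows), "overlap_summary.tsv")

    # 4. length scan with shuffled controls (Fig 1 analogue)
    scan = length_scan(
        data.self_proteome.records, data.nonself_proteomes,
        k_range=range(1, 13), shuffle_seed=derive_seed(seed, "shuffle"),
    )
    write(scan, "length_scan.tsv")

    # 5. cross-reactivity footprint
    fp = average_footprint(RecognitionModel.degenerate(rule))
    write(
        pd.DataFrame(
            [{
                "mean_other_count": fp.mean_other_count,
                "reciprocal": fp.reciprocal,
                "reciprocal_millions": fp.one_in_millions,
                "mean_similar_set_size": rule.mean_set_size,
            }]
        ),
        "footprint.tsv",
    )

    # 6. entropy profile + additional anchors
    profile = position_entropy(self_presented.peptides, allele=allele)
    selectivity, flag = additional_anchor_assessment(profile)
    write(
        pd.DataFrame(
            [{"allele": allele,
              **{f"P{i}": h for i, h in enumerate(profile.entropy, start=1)},
              "non_anchor_selectivity": selectivity,
              "additional_anchors": flag}]
        ),
        "entropy_profile.tsv",
    )

    # 7. immunogenicity association with a planted effect (Table 2 analogue)
    degen = models["degenerate"]
    index = SelfIndex(self_presented.peptides, degen)
    test_peptides = sorted(
        {p for km in nonself_presented for p in km.peptides}
    )
    if len(test_peptides) >= 20:
        flags = [index.overlaps(p) for p in test_peptides]
        labels = synthetic.make_immunogenicity_labels(
            test_peptides, flags, allele=allele, seed=derive_seed(seed, "labels")
        )
        labeled = classify_labels(labels)
        flag_map = dict(zip(labels["peptide"], labels["overlap"]))
        try:
            table = overlap_table(labeled, self_presented.peptides, degen)
            report = association_report(table)
            write(
                pd.DataFrame(
                    [{"a": table.a, "b": table.b, "c": table.c, "d": table.d, **report}]
                ),
                "immunogenicity.tsv",
            )
        except ValueError:
            pass  # degenerate margins on tiny runs: no association table

    manifest = {
        "tool": "pepself",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "config": {k: str(v) for k, v in cfg.items()},
        "config_hash": _config_hash(cfg),
        "n_self_presented": len(self_presented),
        "n_nonself_presented": sum(len(km.peptides) for km in nonself_presented),
        "self_threshold_nm": self_presented.threshold_nm,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
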