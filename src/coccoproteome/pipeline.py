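"""End-to-end orchestration: simulate -> carbonate -> physiology -> inference -> quantification -> report.

One :class:`RunConfig` drives every stage; a fixed seed plus a fixed config
yields byte-identical report files.  Each stage logs its input/output row
counts and the reasons records were dropped; a missing input fails fast with
the stage name and no downstream stage runs on a failed prerequisite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import carbonate, physiology
from .itraq import Design, quantify_experiment, read_psm_table
from .inference import SequenceRecord, cluster_hpgs, map_peptides, tryptic_digest
from .simulate import SimConfig, simulate_all

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run."""

    outdir: str = "pipeline_out"
    seed: int = 0
    salinity_default: float = 35.0
    ci_z: float = 1.96
    up_threshold: float = 1.5
    down_threshold: float = 0.67
    e_threshold: float = 1.00e-10
    min_identity: float = 5.0
    include_nutrients: bool = False
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        if not (0 < self.down_threshold < 1 < self.up_threshold):
            raise ValueError("need down_threshold < 1 < up_threshold, all positive")
        if self.e_threshold <= 0 or self.min_identity < 0:
            raise ValueError("clustering thresholds must be positive")
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_kwargs = raw.pop("sim", {})
        cfg = cls(**raw)
        for k, v in sim_kwargs.items():
            setattr(cfg.sim, k, v)
        cfg.sim.seed = cfg.seed
        return cfg


def _read_fasta(path, alphabet: str, source_db: str) -> list[SequenceRecord]:
    from Bio import SeqIO

    return [
        SequenceRecord(id=rec.id, residues=str(rec.seq), alphabet=alphabet, source_db=source_db)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order and write the report bundle.

    Returns a dict of output paths.  Stage order: synthetic-data generation,
    carbonate speciation of the bottle samples, physiology summary with
    between-condition t-tests, peptide mapping + HPG clustering, iTRAQ
    quantification and regulation calls, and a combined human-readable
    summary.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate: writing synthetic inputs to %s", out / "data")
    paths = simulate_all(config.sim, out / "data")

    # --- carbonate
    stage = "carbonate"
    bottles = pd.read_csv(paths["bottles"], sep="\t")
    logger.info("stage %s: %d bottle samples", stage, len(bottles))
    speciation = carbonate.solve_table(
        bottles, config.salinity_default, include_nutrients=config.include_nutrients
    )
    blanks = speciation[speciation.sample_id.str.endswith("blank")].set_index("condition")
    drawdown = [
        {
            "sample_id": r.sample_id,
            "percent_dic_drawdown": carbonate.percent_dic_drawdown(
                r.dic_umol_kg, blanks.loc[r.condition, "dic_umol_kg"]
            ),
        }
        for r in speciation.itertuples()
        if not r.sample_id.endswith("blank")
    ]
    speciation = speciation.merge(pd.DataFrame(drawdown), on="sample_id", how="left")
    speciation_path = out / "speciation.tsv"
    speciation.to_csv(speciation_path, sep="\t", index=False)

    # --- physiology
    stage = "physiology"
    culture = pd.read_csv(paths["culture"], sep="\t")
    truth = pd.read_csv(paths["truth"], sep="\t")
    qt = truth[(truth.entity_type == "culture") & truth.parameter.str.startswith("quota_")]
    quotas = pd.DataFrame(
        {
            "condition": qt.entity_id.str.split("/").str[0],
            "replicate": qt.entity_id.str.split("/").str[1].astype(int),
            "analyte": qt.parameter.str.removeprefix("quota_"),
            "quota": qt.value.astype(float),
        }
    )
    logger.info("stage %s: %d culture rows, %d quota rows", stage, len(culture), len(quotas))
    physio = physiology.summarize_culture(culture, quotas)
    tests = []
    for col in [c for c in physio.columns if c not in ("condition", "replicate")]:
        groups = {
            cond: physiology.morphometry_summary(sub[col].dropna())
            for cond, sub in physio.groupby("condition")
            if sub[col].notna().sum() >= 2
        }
        if {"ambient", "high"} <= set(groups):
            res = physiology.pooled_t_test(groups["ambient"], groups["high"])
            tests.append({"parameter": col, "t": res.t, "df": res.df, "p": res.p})
    physio_path = out / "physiology.tsv"
    physio.to_csv(physio_path, sep="\t", index=False)
    ttest_path = out / "physiology_ttests.tsv"
    pd.DataFrame(tests).to_csv(ttest_path, sep="\t", index=False)

    # --- inference
    stage = "inference"
    prot_db = _read_fasta(paths["families"], "amino-acid", "genome")
    est_db = _read_fasta(paths["ests"], "nucleotide", "est")
    peptides = {
        p for rec in prot_db for p in tryptic_digest(rec.residues, missed_cleavages=0)
    }
    idents = map_peptides(peptides, prot_db + est_db)
    logger.info(
        "stage %s: %d peptides mapped to %d identifications", stage, len(peptides), len(idents)
    )
    seqs = {r.id: r.residues for r in prot_db}
    for r in est_db:
        # cluster ESTs on their best-frame translation
        from .inference import six_frame_translate

        frames = six_frame_translate(r)
        best = max(
            (seg for fr in frames for seg in fr.split("*")), key=len, default=""
        )
        seqs[r.id] = best or "X"
    hpgs = cluster_hpgs(
        idents, seqs, e_threshold=config.e_threshold, min_identity=config.min_identity
    )
    hpg_rows = [
        {
            "hpg_id": h.hpg_id,
            "member_id": m,
            "source_db": next(p.source_db for p in idents if p.id == m),
            "representative": h.representative,
            "n_peptides": h.n_peptides[m],
        }
        for h in hpgs
        for m in h.members
    ]
    hpg_path = out / "hpgs.tsv"
    pd.DataFrame(hpg_rows).to_csv(hpg_path, sep="\t", index=False)
    logger.info("stage %s: %d HPGs from %d identifications", stage, len(hpgs), len(idents))

    # --- quantification
    stage = "quantification"
    psms = read_psm_table(paths["psms"])
    pep_map = {}
    for rec in prot_db:
        for p in tryptic_digest(rec.residues):
            pep_map.setdefault(p, rec.id)
    logger.info("stage %s: %d PSMs", stage, len(psms))
    calls = quantify_experiment(
        psms, Design(), pep_map, z=config.ci_z
    )
    calls_path = out / "calls.tsv"
    calls.to_csv(calls_path, sep="\t", index=False)

    # --- report
    n_up = int((calls.regulation == "up").sum())
    n_down = int((calls.regulation == "down").sum())
    n_ne = int((calls.regulation == "not_evaluable").sum())
    report_path = out / "report.txt"
    with open(report_path, "w") as fh:
        fh.write("pipeline report\n===============\n\n")
        fh.write(f"seed: {config.seed}\n\n")
        fh.write("carbonate speciation (per bottle):\n")
        fh.write(speciation.to_string(index=False))
        fh.write("\n\nphysiology (per replicate):\n")
        fh.write(physio.to_string(index=False))
        fh.write("\n\nbetween-condition t-tests:\n")
        fh.write(pd.DataFrame(tests).to_string(index=False))
        fh.write(
            f"\n\nhomologous protein groups: {len(hpgs)} "
            f"from {len(idents)} identifications\n"
        )
        fh.write(
            f"\nregulation calls: {len(calls)} proteins, "
            f"{n_up} up, {n_down} down, {n_ne} not evaluable\n"
        )
    logger.info("report written to %s", report_path)

    return {
        "speciation": speciation_path,
        "physiology": physio_path,
        "ttests": ttest_path,
        "hpgs": hpg_path,
        "calls": calls_path,
        "report": report_path,
        **paths,
    }
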