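"""Synthetic inputs with known ground truth for every pipeline stage.

Generates what the real experiment produced, at the same scale and under the
same design, with the truth recorded so recovery is testable:

* protein families (random ancestors, point-mutated members) and their
  reverse-translated EST databases with optional frameshifts and strand
  flips — exercising six-frame searching;
* 8-plex reporter-ion PSM tables: per-peptide base intensity is log-normal,
  each channel is scaled by a channel loading bias, high-CO2 channels by the
  protein's true fold change, and every channel carries multiplicative
  log-normal noise (additive Gaussian on log ratios, matching the
  geometric-mean statistics used downstream);
* exponential batch cultures for the two CO2 conditions (triplicate, ~4
  generations to harvest, <5% DIC drawdown relative to the cell-free blank)
  with per-cell quotas and carbonate bottle samples.

All randomness flows from one integer seed through named `numpy` substreams,
so a fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .itraq import Design

__all__ = [
    "SimConfig",
    "TruthTable",
    "make_protein_families",
    "reverse_translate_to_ests",
    "simulate_psms",
    "simulate_culture",
    "simulate_all",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# standard genetic code, inverted: residue -> synonymous codons
_CODONS: dict[str, list[str]] = {}
_BASES = "TCAG"
_TABLE = (
    "FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR" "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG"
)
for _i, _aa in enumerate(_TABLE):
    _codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    _CODONS.setdefault(_aa, []).append(_codon)


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the study's design.

    Three replicate high:ambient channel pairs, 46 quantified proteins of
    which four are down-regulated at a true fold change of 0.4, log-normal
    reporter noise of 0.15 on the natural-log scale per channel, ±20%
    channel loading biases, triplicate cultures harvested after ~4
    generations with <5% DIC drawdown.
    """

    seed: int = 0
    # sequence families
    n_families: int = 16
    members_per_family: int = 3
    family_divergence: float = 0.30  # substitution fraction per member
    length_range: tuple = (150, 400)
    # quantification
    n_proteins_quantified: int = 46
    peptides_per_protein: int = 5
    sigma_noise: float = 0.15
    channel_bias: dict | None = None  # tag -> multiplier; None = random ±20%
    fold_changes: dict | None = None  # protein -> true ratio; None = 4 down at 0.4
    n_down: int = 4
    down_fold_change: float = 0.4
    base_intensity_mu: float = math.log(1e4)
    base_intensity_sigma: float = 0.5
    # cultures
    mu_ambient: float = 1.29  # day-1
    mu_high: float = 1.05
    n0: float = 5e3  # inoculation density, cells mL-1
    harvest_generations: float = 4.0
    quotas: dict = field(
        default_factory=lambda: {
            # pmol cell-1 (mean, sd) per condition
            "ambient": {"POC": (1.37, 0.13), "PON": (0.21, 0.02), "CaCO3": (1.37, 0.15)},
            "high": {"POC": (1.84, 0.22), "PON": (0.28, 0.03), "CaCO3": (1.84, 0.25)},
        }
    )
    dic_drawdown_fraction: float = 0.04
    blank_dic: dict = field(
        default_factory=lambda: {"ambient": 2043.8, "high": 2252.6}
    )
    blank_ta: dict = field(default_factory=lambda: {"ambient": 2291.0, "high": 2302.8})
    temperature: float = 19.0
    salinity: float = 35.0
    n_replicates: int = 3
    density_noise: float = 0.03  # lognormal sd on counted densities

    def rng(self, stream: str) -> np.random.Generator:
        """Named deterministic substream derived from the master seed."""
        tag = int.from_bytes(stream.encode(), "little") % (2**31)
        return np.random.default_rng([self.seed % (2**31), tag])


@dataclass
class TruthTable:
    """Ground truth for everything generated."""

    proteins: pd.DataFrame  # protein_id, family_id, fold_change
    cultures: pd.DataFrame  # condition, replicate, mu, quota_<analyte>...

    def to_tsv(self, path) -> None:
        """Single long-format TSV: entity_type, entity_id, parameter, value."""
        rows = []
        for _, r in self.proteins.iterrows():
            rows.append(("protein", r.protein_id, "family_id", r.family_id))
            rows.append(("protein", r.protein_id, "fold_change", r.fold_change))
        for _, r in self.cultures.iterrows():
            eid = f"{r.condition}/{r.replicate}"
            for col in self.cultures.columns:
                if col not in ("condition", "replicate"):
                    rows.append(("culture", eid, col, r[col]))
        pd.DataFrame(rows, columns=["entity_type", "entity_id", "parameter", "value"]).to_csv(
            path, sep="\t", index=False
        )


def _write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def make_protein_families(config: SimConfig):
    """Random protein families: uniform ancestors, point-mutated members.

    Returns ``(records, truth)`` where records are ``(id, sequence)`` pairs
    named ``F<f>M<m>`` and truth maps each member to its family.  Member
    sequences differ from the ancestor at ``family_divergence`` of positions
    (substitutions to a different residue, so pairwise identity between two
    members is about ``(1 - d)**2 + d * d / 19``).
    """
    rng = config.rng("families")
    records = []
    rows = []
    for f in range(config.n_families):
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        ancestor = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        for m in range(config.members_per_family):
            seq = list(ancestor)
            n_mut = int(round(config.family_divergence * length))
            sites = rng.choice(length, size=n_mut, replace=False) if n_mut else []
            for s in sites:
                choices = [a for a in AMINO_ACIDS if a != seq[s]]
                seq[s] = choices[int(rng.integers(len(choices)))]
            rid = f"F{f:03d}M{m}"
            records.append((rid, "".join(seq)))
            rows.append({"protein_id": rid, "family_id": f"F{f:03d}", "fold_change": 1.0})
    return records, pd.DataFrame(rows)


def reverse_translate_to_ests(
    proteins: list[tuple[str, str]],
    frameshift_prob: float = 0.0,
    per_base_error: float = 0.0,
    seed: int = 0,
    flip_prob: float = 0.5,
):
    """Reverse-translate proteins into EST-like nucleotide reads.

    Codons are drawn uniformly among synonyms; with ``frameshift_prob`` a
    single-nucleotide insertion lands at a random position (breaking the
    reading frame downstream); records are strand-flipped with
    ``flip_prob``.  Returns ``(records, truth)`` with truth recording the
    strand and frameshift position of each EST.
    """
    rng = np.random.default_rng([seed % (2**31), 0x0E57])
    records, rows = [], []
    for pid, aa in proteins:
        nt = "".join(_CODONS[res][int(rng.integers(len(_CODONS[res])))] for res in aa)
        if per_base_error > 0:
            bases = list(nt)
            for i in range(len(bases)):
                if rng.random() < per_base_error:
                    bases[i] = "TCAG"[int(rng.integers(4))]
            nt = "".join(bases)
        shift_pos = -1
        if rng.random() < frameshift_prob:
            shift_pos = int(rng.integers(1, len(nt)))
            nt = nt[:shift_pos] + "TCAG"[int(rng.integers(4))] + nt[shift_pos:]
        flipped = bool(rng.random() < flip_prob)
        if flipped:
            comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
            nt = "".join(comp[b] for b in reversed(nt))
        rid = f"EST_{pid}"
        records.append((rid, nt))
        rows.append(
            {"est_id": rid, "protein_id": pid, "flipped": flipped, "frameshift_pos": shift_pos}
        )
    return records, pd.DataFrame(rows)


def _tryptic_peptides(aa: str, k: int) -> list[str]:
    from .inference import tryptic_digest

    return tryptic_digest(aa, missed_cleavages=0, min_length=6)[:k]


def simulate_psms(
    proteins: list[tuple[str, str]],
    design: Design | None = None,
    config: SimConfig | None = None,
):
    """Reporter-ion PSM table for the 8-plex design, plus fold-change truth.

    Only the first ``n_proteins_quantified`` proteins with at least
    ``peptides_per_protein`` usable tryptic peptides are quantified.  The
    true fold change multiplies the high-CO2 channels (114, 116, 118, 121)
    identically; channel biases multiply whole channels; every channel value
    carries independent log-normal noise exp(N(0, sigma_noise)).
    """
    config = config or SimConfig()
    design = design or Design()
    rng = config.rng("psms")

    high_tags = {hi for hi, _ in design.replicate_pairs} | {121}
    tags = (113, 114, 115, 116, 117, 118, 119, 121)

    if config.channel_bias is None:
        bias = {t: float(b) for t, b in zip(tags, rng.uniform(0.8, 1.2, size=len(tags)))}
    else:
        bias = dict(config.channel_bias)

    usable = [(pid, aa) for pid, aa in proteins if len(_tryptic_peptides(aa, 10**9)) >= 1]
    usable = usable[: config.n_proteins_quantified]

    if config.fold_changes is None:
        fc = {pid: 1.0 for pid, _ in usable}
        for pid, _ in usable[: config.n_down]:
            fc[pid] = config.down_fold_change
    else:
        fc = {pid: config.fold_changes.get(pid, 1.0) for pid, _ in usable}

    rows = []
    spec_no = 0
    for pid, aa in usable:
        for pep in _tryptic_peptides(aa, config.peptides_per_protein):
            spec_no += 1
            base = float(
                np.exp(rng.normal(config.base_intensity_mu, config.base_intensity_sigma))
            )
            row = {"spectrum_id": f"S{spec_no:06d}", "peptide": pep, "source_id": pid}
            for t in tags:
                val = base * bias[t]
                if t in high_tags:
                    val *= fc[pid]
                val *= float(np.exp(rng.normal(0.0, config.sigma_noise)))
                row[f"i{t}"] = round(val, 3)
            rows.append(row)
    psms = pd.DataFrame(rows)
    truth = pd.DataFrame(
        [{"protein_id": pid, "family_id": "", "fold_change": fc[pid]} for pid, _ in usable]
    )
    return psms, truth


def simulate_culture(config: SimConfig | None = None):
    """Daily culture counts, harvest bottle chemistry and quota truth.

    Densities follow N(t) = N0 * exp(mu t) sampled daily until the harvest
    generation count is reached, with multiplicative log-normal counting
    noise; bottle DIC at harvest is (1 - drawdown) * blank DIC; quotas are
    drawn from truncated normals per condition.
    """
    config = config or SimConfig()
    rng = config.rng("culture")
    mu = {"ambient": config.mu_ambient, "high": config.mu_high}

    culture_rows, bottle_rows, truth_rows = [], [], []
    for cond in ("ambient", "high"):
        t_harvest = config.harvest_generations * math.log(2) / mu[cond]
        days = [float(d) for d in range(int(math.floor(t_harvest)) + 1)]
        if days[-1] < t_harvest:
            days.append(round(t_harvest, 3))  # harvest sample at the exact time
        for rep in range(1, config.n_replicates + 1):
            for day in days:
                n_true = config.n0 * math.exp(mu[cond] * day)
                noise = float(np.exp(rng.normal(0.0, config.density_noise))) if config.density_noise else 1.0
                vol = 52.0 if cond == "ambient" else 69.4
                culture_rows.append(
                    {
                        "condition": cond,
                        "replicate": rep,
                        "day": day,
                        "cell_density": n_true * noise,
                        "coccosphere_volume": vol * float(np.exp(rng.normal(0.0, 0.02))),
                    }
                )
            truth = {"condition": cond, "replicate": rep, "mu": mu[cond]}
            for analyte, (qm, qs) in config.quotas[cond].items():
                q = max(0.0, float(rng.normal(qm, qs)))
                truth[f"quota_{analyte}"] = q
            truth_rows.append(truth)
            bottle_rows.append(
                {
                    "sample_id": f"{cond}_rep{rep}_harvest",
                    "condition": cond,
                    "dic_umol_kg": round(
                        (1.0 - config.dic_drawdown_fraction) * config.blank_dic[cond], 1
                    ),
                    "ta_umol_kg": config.blank_ta[cond],
                    "temperature_c": config.temperature,
                    "salinity": config.salinity,
                }
            )
        bottle_rows.append(
            {
                "sample_id": f"{cond}_blank",
                "condition": cond,
                "dic_umol_kg": config.blank_dic[cond],
                "ta_umol_kg": config.blank_ta[cond],
                "temperature_c": config.temperature,
                "salinity": config.salinity,
            }
        )
    culture = pd.DataFrame(culture_rows)
    bottles = pd.DataFrame(bottle_rows)
    truth = pd.DataFrame(truth_rows)
    return culture, bottles, truth


def simulate_all(config: SimConfig, outdir) -> dict:
    """Write every synthetic input the pipeline consumes into ``outdir``.

    Files: families.faa, ests.fna, psms.tsv, design.yaml, culture.tsv,
    bottles.tsv, truth.tsv.  Returns the paths keyed by stage.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fam_records, fam_truth = make_protein_families(config)
    _write_fasta(fam_records, outdir / "families.faa")
    est_records, _est_truth = reverse_translate_to_ests(
        fam_records, frameshift_prob=0.2, seed=config.seed
    )
    _write_fasta(est_records, outdir / "ests.fna")

    design = Design()
    psms, prot_truth = simulate_psms(fam_records, design, config)
    psms.to_csv(outdir / "psms.tsv", sep="\t", index=False)
    with open(outdir / "design.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "replicate_pairs": [list(p) for p in design.replicate_pairs],
                "excluded_tags": sorted(design.excluded_tags),
            },
            fh,
        )

    culture, bottles, cult_truth = simulate_culture(config)
    culture.to_csv(outdir / "culture.tsv", sep="\t", index=False)
    bottles.to_csv(outdir / "bottles.tsv", sep="\t", index=False)

    fam_map = dict(zip(fam_truth.protein_id, fam_truth.family_id))
    prot_truth["family_id"] = prot_truth.protein_id.map(fam_map).fillna("")
    TruthTable(proteins=prot_truth, cultures=cult_truth).to_tsv(outdir / "truth.tsv")

    return {
        "families": outdir / "families.faa",
        "ests": outdir / "ests.fna",
        "psms": outdir / "psms.tsv",
        "design": outdir / "design.yaml",
        "culture": outdir / "culture.tsv",
        "bottles": outdir / "bottles.tsv",
        "truth": outdir / "truth.tsv",
    }
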