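"""Six-frame translation, digestion, peptide mapping, alignment, HPG clustering."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from coccoproteome.inference import (
    SequenceRecord,
    cluster_hpgs,
    local_align,
    map_peptides,
    six_frame_translate,
    tryptic_digest,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _nt(seq, rid="n1"):
    return SequenceRecord(id=rid, residues=seq, alphabet="nucleotide", source_db="est")


def test_six_frame_basic():
    frames = six_frame_translate(_nt("ATGAAA"))
    assert frames[0] == "MK"
    assert frames[3] == "FH"  # reverse complement TTTCAT, frame 1
    assert len(frames) == 6


def test_six_frame_short_input():
    frames = six_frame_translate(_nt("ATGAA"))
    assert frames[0] == "M"
    assert frames[1] == "*"  # offset 1: single codon TGA
    assert frames[2] == "E"  # offset 2: single codon GAA
    assert len(frames) == 6


def test_six_frame_reverse_complement_permutes_frames():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=90))
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    rc = "".join(comp[b] for b in reversed(seq))
    f1 = six_frame_translate(_nt(seq))
    f2 = six_frame_translate(_nt(rc))
    assert sorted(f1) == sorted(f2)
    assert f2[0] == f1[3] and f2[3] == f1[0]


def test_six_frame_rejects_amino_acid_record():
    with pytest.raises(ValueError):
        six_frame_translate(SequenceRecord(id="p", residues="MKR", alphabet="amino-acid"))


def test_tryptic_digest_rule():
    assert tryptic_digest("MKRAGKPLR", 0, min_length=1) == ["MK", "R", "AGKPLR"]
    assert tryptic_digest("MKRAGKPLR", 0) == ["AGKPLR"]  # default min length 6


def test_tryptic_digest_missed_cleavages():
    peps = set(tryptic_digest("MKRAGKPLR", 1, min_length=1))
    assert {"MKR", "RAGKPLR"} <= peps


def test_tryptic_digest_no_cleavage_site():
    assert tryptic_digest("AAAAAAA", 0) == ["AAAAAAA"]


def test_map_peptides_two_peptide_rule():
    db = [
        SequenceRecord("good", "AAAAEEEKGGGGFFFFKMMMM", source_db="genome"),
        SequenceRecord("single", "AAAAEEEKWWWWWWWW", source_db="genome"),
    ]
    peps = {"AAAAEEEK", "GGGGFFFFK"}
    out = map_peptides(peps, db)
    ids = {p.id for p in out}
    assert ids == {"good"}
    good = out[0]
    assert good.n_distinct_peptides == 2
    assert good.shared_peptides == {"AAAAEEEK"}  # matched both records


def test_map_peptides_searches_est_frames():
    # reverse-complemented coding sequence for "MAAAEEEKGGGGFFFFK..."
    protein = "MAAAEEEKGGGGFFFFK"
    codon = {"M": "ATG", "A": "GCT", "E": "GAA", "K": "AAA", "G": "GGT", "F": "TTT"}
    nt = "".join(codon[c] for c in protein)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    rc = "".join(comp[b] for b in reversed(nt))
    out = map_peptides({"MAAAEEEK", "GGGGFFFFK"}, [_nt(rc, "est1")])
    assert [p.id for p in out] == ["est1"]


def _gotoh_local(a, b, gap_open=11, gap_extend=1):
    """Independent affine-gap Smith-Waterman oracle (full DP, small inputs)."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
            M[i, j] = max(0.0, M[i - 1, j - 1] + s, X[i, j], Y[i, j])
            best = max(best, M[i, j])
    return best


def test_local_align_identical_sequences():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list(AA), size=100))
    res = local_align(seq, seq)
    assert res.identity == 100.0
    assert res.e_value < 1e-10


def test_local_align_random_pairs_not_significant():
    """Unrelated length-50 sequences stay above the 1e-10 e-value cutoff."""
    rng = np.random.default_rng(2)
    n_sig = 0
    for _ in range(100):
        a = "".join(rng.choice(list(AA), size=50))
        b = "".join(rng.choice(list(AA), size=50))
        if local_align(a, b).e_value <= 1e-10:
            n_sig += 1
    assert n_sig == 0


def test_local_align_score_matches_dp_oracle():
    rng = np.random.default_rng(3)
    for _ in range(25):
        a = "".join(rng.choice(list(AA), size=int(rng.integers(8, 31))))
        b = "".join(rng.choice(list(AA), size=int(rng.integers(8, 31))))
        assert local_align(a, b).score == pytest.approx(_gotoh_local(a, b))


def _mutate(seq, frac, rng):
    out = list(seq)
    sites = rng.choice(len(seq), size=int(round(frac * len(seq))), replace=False)
    for s in sites:
        out[s] = rng.choice([c for c in AA if c != out[s]])
    return "".join(out)


def test_divergent_pair_identity_near_target():
    """A pair mutated at 30% each from an ancestor shows ~(0.7^2)*100 = 49%
    + random coincidences identity, within ±10 points."""
    rng = np.random.default_rng(4)
    anc = "".join(rng.choice(list(AA), size=200))
    a, b = _mutate(anc, 0.3, rng), _mutate(anc, 0.3, rng)
    res = local_align(a, b)
    expected = 100 * (0.7**2 + 2 * 0.7 * 0.3 / 19 + (0.3**2) / 19)
    assert abs(res.identity - expected) < 10


def _ident(rid, seq, db="genome"):
    from coccoproteome.inference import IdentifiedProtein

    return IdentifiedProtein(id=rid, source_db=db, matched_peptides=frozenset({"A" * 6, "C" * 6}))


def test_cluster_duplicates_form_one_hpg():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list(AA), size=120))
    idents = [_ident("x1", seq), _ident("x2", seq, db="uniprot")]
    hpgs = cluster_hpgs(idents, {"x1": seq, "x2": seq})
    assert len(hpgs) == 1
    assert hpgs[0].members == ("x1", "x2")
    assert set(hpgs[0].source_dbs) == {"genome", "uniprot"}


def test_cluster_unrelated_sequences_stay_singletons():
    rng = np.random.default_rng(6)
    a = "".join(rng.choice(list(AA), size=50))
    b = "".join(rng.choice(list(AA), size=50))
    hpgs = cluster_hpgs([_ident("a", a), _ident("b", b)], {"a": a, "b": b})
    assert len(hpgs) == 2


def test_cluster_family_plus_outlier():
    rng = np.random.default_rng(7)
    anc = "".join(rng.choice(list(AA), size=180))
    seqs = {f"m{i}": _mutate(anc, 0.2, rng) for i in range(4)}
    seqs["out"] = "".join(rng.choice(list(AA), size=180))
    idents = [_ident(k, v) for k, v in seqs.items()]
    hpgs = cluster_hpgs(idents, seqs)
    sizes = sorted(len(h.members) for h in hpgs)
    assert sizes == [1, 4]


def test_cluster_is_partition_and_order_invariant():
    rng = np.random.default_rng(8)
    anc1 = "".join(rng.choice(list(AA), size=150))
    anc2 = "".join(rng.choice(list(AA), size=150))
    seqs = {}
    for i in range(3):
        seqs[f"a{i}"] = _mutate(anc1, 0.15, rng)
        seqs[f"b{i}"] = _mutate(anc2, 0.15, rng)
    idents = [_ident(k, v) for k, v in seqs.items()]
    h1 = cluster_hpgs(idents, seqs)
    h2 = cluster_hpgs(list(reversed(idents)), seqs)
    assert {h.members for h in h1} == {h.members for h in h2}
    all_members = [m for h in h1 for m in h.members]
    assert sorted(all_members) == sorted(seqs)  # partition: each id exactly once
    assert [h.hpg_id for h in h1] == sorted(h.hpg_id for h in h1)


def test_cluster_recovers_truth_partition():
    """ARI = 1 against generator truth for families at <= 40% divergence."""
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(9)
    seqs, truth = {}, []
    for f in range(5):
        anc = "".join(rng.choice(list(AA), size=160))
        for m in range(3):
            seqs[f"f{f}m{m}"] = _mutate(anc, 0.4, rng)
            truth.append(f)
    idents = [_ident(k, v) for k, v in seqs.items()]
    hpgs = cluster_hpgs(idents, seqs)
    label = {m: i for i, h in enumerate(hpgs) for m in h.members}
    pred = [label[k] for k in seqs]
    assert adjusted_rand_score(truth, pred) == 1.0


def test_cluster_representative_is_longest_member():
    rng = np.random.default_rng(10)
    anc = "".join(rng.choice(list(AA), size=150))
    seqs = {"short": anc[:120], "long": anc}
    hpgs = cluster_hpgs([_ident("short", seqs["short"]), _ident("long", anc)], seqs)
    assert len(hpgs) == 1 and hpgs[0].representative == "long"
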