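"""PDB text-record mining, hashed embedding, balancing and classification."""

import numpy as np
import pytest

from murzyme.pdbtext import (
    EmbedderConfig,
    LabeledCorpus,
    PDBFormatError,
    PDBTextRecord,
    balance_by_oversampling,
    balance_by_undersampling,
    embed,
    embed_corpus,
    extract_text_features,
    split_train_test,
    train_eval,
)

SAMPLE_PDB = (
    "HEADER    OXIDOREDUCTASE                          12-MAY-99   1ABC\n"
    "TITLE     CHLOROPEROXIDASE FROM CALDARIOMYCES FUMAGO IN COMPLEX WITH\n"
    "TITLE    2 A HALIDE ION\n"
    "COMPND    MOL_ID: 1;\n"
    "COMPND   2 MOLECULE: CHLOROPEROXIDASE LONG NAME THAT\n"
    "COMPND   3 CONTINUES HERE;\n"
    "COMPND   4 CHAIN: A\n"
    "KEYWDS    OXIDOREDUCTASE, HEME, PEROXIDASE\n"
    "HET    HEM  A 401      43\n"
    "HETNAM     HEM PROTOPORPHYRIN IX CONTAINING FE\n"
    "END\n"
)


def test_extract_all_record_kinds():
    rec = extract_text_features(SAMPLE_PDB)
    assert rec.entry_id == "1ABC"
    assert rec.classification == "oxidoreductase"
    assert rec.keywords == ("oxidoreductase", "heme", "peroxidase")
    # two-line COMPND continuation joins into one molecule name, space intact
    assert rec.molecules == ("chloroperoxidase long name that continues here",)
    assert "halide ion" in rec.title
    assert rec.het_codes == ("HEM",)
    assert rec.text.islower() and "," not in rec.text


def test_missing_optional_records_yield_empty_fields():
    rec = extract_text_features("HEADER    HYDROLASE                               01-JAN-20   2XYZ\n")
    assert rec.keywords == () and rec.molecules == () and rec.title == ""
    assert rec.classification == "hydrolase"


def test_non_pdb_input_rejected():
    with pytest.raises(PDBFormatError):
        extract_text_features(">seq1\nMKTAYIAKQR\n")


def test_extract_accepts_path(tmp_path):
    p = tmp_path / "x.pdb"
    p.write_text(SAMPLE_PDB)
    assert extract_text_features(p) == extract_text_features(SAMPLE_PDB)


def test_extract_matches_biopython_header_parser(tmp_path):
    """Independent cross-check on the fields biopython parses faithfully."""
    from Bio.PDB import parse_pdb_header

    p = tmp_path / "x.pdb"
    p.write_text(SAMPLE_PDB)
    theirs = parse_pdb_header(str(p))
    ours = extract_text_features(p)
    assert ours.classification == theirs["head"].strip()
    assert list(ours.keywords) == [k.strip() for k in theirs["keywords"].split(",")]


def test_embed_properties():
    cfg = EmbedderConfig(dimension=384)
    assert embed("", cfg).shape == (384,)
    assert np.linalg.norm(embed("", cfg)) == 0.0
    v1 = embed("heme peroxidase oxidoreductase", cfg)
    v2 = embed("heme peroxidase oxidoreductase", cfg)
    assert np.array_equal(v1, v2)
    assert np.linalg.norm(v1) == pytest.approx(1.0)
    assert embed("heme", EmbedderConfig(dimension=16)).shape == (16,)


def test_embedder_is_stable_across_processes():
    # frozen reference values guard the hash against platform drift
    v = embed("heme", EmbedderConfig(dimension=8))
    assert int(np.argmax(v)) == 7 and v[7] == 1.0


def test_external_embedder_plug_in(default_corpus):
    calls = {}

    def fake(texts):
        calls["n"] = len(texts)
        return np.ones((len(texts), 4))

    cfg = EmbedderConfig(dimension=4, kind="external-sentence-embedding", external_fn=fake)
    X = embed_corpus(default_corpus, cfg)
    assert X.shape == (len(default_corpus), 4)
    assert calls["n"] == len(default_corpus)
    with pytest.raises(ValueError, match="external embedder requires"):
        EmbedderConfig(kind="external-sentence-embedding")


def _corpus(n_m, n_c):
    recs = [PDBTextRecord(f"r{i}", "", "", (), (), (), f"tok{i}")
            for i in range(n_m + n_c)]
    return LabeledCorpus(recs, ["murzyme"] * n_m + ["classical"] * n_c)


@pytest.mark.parametrize("n_m, n_c, expected", [(10, 30, (30, 30)), (20, 20, (20, 20)),
                                                (116, 294, (294, 294))])
def test_oversampling_reaches_parity(n_m, n_c, expected):
    out = balance_by_oversampling(_corpus(n_m, n_c), seed=0)
    assert (out.class_counts["murzyme"], out.class_counts["classical"]) == expected


def test_undersampling_reaches_parity():
    out = balance_by_undersampling(_corpus(10, 30), seed=0)
    assert out.class_counts == {"classical": 10, "murzyme": 10}


def test_balancing_single_class_rejected():
    with pytest.raises(ValueError):
        balance_by_oversampling(LabeledCorpus(_corpus(3, 1).records[:3], ["murzyme"] * 3))


def test_split_is_stratified_disjoint_and_seeded(default_corpus):
    tr1, te1 = split_train_test(default_corpus, test_frac=0.2, seed=4)
    tr2, te2 = split_train_test(default_corpus, test_frac=0.2, seed=4)
    assert [r.entry_id for r in te1.records] == [r.entry_id for r in te2.records]
    ids_tr = {r.entry_id for r in tr1.records}
    ids_te = {r.entry_id for r in te1.records}
    assert not ids_tr & ids_te
    assert len(ids_tr | ids_te) == len(default_corpus)
    assert len(te1) == 40  # 4:1 split of 200
    # stratification preserves the 56/144 imbalance on both sides
    assert te1.class_counts == {"classical": 29, "murzyme": 11}
    with pytest.raises(ValueError):
        split_train_test(default_corpus, test_frac=0.0)


def test_oversampling_does_not_touch_test_partition(default_corpus):
    train, test = split_train_test(default_corpus, seed=1)
    before = [(r.entry_id, l) for r, l in zip(test.records, test.labels)]
    balance_by_oversampling(train, seed=1)
    after = [(r.entry_id, l) for r, l in zip(test.records, test.labels)]
    assert before == after


def test_separable_corpus_all_models_perfect(separable_corpus):
    for model in ("svm", "logistic", "forest"):
        s = train_eval(separable_corpus, model=model, n_reps=3, seed=2)
        assert s.accuracy_mean == 1.0


def test_random_labels_near_chance(default_corpus):
    rng = np.random.default_rng(3)
    shuffled = LabeledCorpus(
        default_corpus.records,
        [["murzyme", "classical"][b] for b in rng.integers(0, 2, len(default_corpus))],
    )
    s = train_eval(shuffled, model="svm", n_reps=5, seed=3)
    assert abs(s.accuracy_mean - 0.5) < 0.15


def test_train_eval_rejects_unknown_model(default_corpus):
    with pytest.raises(ValueError, match="unknown model"):
        train_eval(default_corpus, model="perceptron", n_reps=1)
    with pytest.raises(ValueError, match="balance"):
        train_eval(default_corpus, balance="smote", n_reps=1)


def test_train_eval_seed_determinism(default_corpus):
    a = train_eval(default_corpus, model="svm", n_reps=2, seed=11)
    b = train_eval(default_corpus, model="svm", n_reps=2, seed=11)
    assert a == b
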