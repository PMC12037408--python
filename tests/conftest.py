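import io

import pytest

import trnachimera as T
from trnachimera import synth as SY
from trnachimera.synth import HOST_BACKBONE


def make_record(gene_id="g1", organism="org", isoacceptor="Trp", **part_overrides):
    """A raw record based on the cloverleaf-stable consensus backbone."""
    parts = dict(HOST_BACKBONE)
    parts.update(part_overrides)
    anticodon = parts["ac_loop"][2:5]
    return T.TrnaRecord(
        gene_id=gene_id,
        organism=organism,
        isoacceptor=isoacceptor,
        anticodon=anticodon,
        parts=parts,
    )


def db_roundtrip(df):
    """Parse a synthetic DataFrame the way the CLI would (via TSV text)."""
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return T.parse_db(buf)


@pytest.fixture(scope="session")
def default_table():
    return T.default_identity_table()


@pytest.fixture(scope="session")
def synth_trp():
    """A cleaned synthetic Trp database with its manifest and host table."""
    cfg = SY.SynthConfig(
        n_organisms=60,
        isoacceptors=("Trp",),
        corruption_rate=0.1,
        n_identity_groups=4,
        seed=17,
    )
    df, manifest = SY.make_db(cfg)
    raw, parse_rejects = db_roundtrip(df)
    cleaned, clean_rejects = T.cleanup(raw)
    return {
        "config": cfg,
        "df": df,
        "manifest": manifest,
        "cleaned": cleaned,
        "rejects": parse_rejects + clean_rejects,
        "table": SY.make_identity_table(cfg),
    }
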