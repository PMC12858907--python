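"""Regenerate tests/data/oracle_baseline.tsv.

Computes the optima of the hand-designed fixtures with the brute-force
vertex-enumeration reference solver (never the production solver) and
freezes them as the test baseline.  Run from the repository root:

    python scripts/make_oracle_baseline.py
"""

from pathlib import Path

import pandas as pd

from gemcom import Medium, ObjectiveSpec, assemble_community
from gemcom.oracle import oracle_community, oracle_fba
from gemcom.synth import chain_strain, cross_feeder_pair, dhp_spec, make_designed_consortium


def main() -> None:
    rows = []

    t1 = chain_strain()
    rows.append(("t1_glc10_fba", oracle_fba(t1, Medium("glc10", {"glc": 10}))))
    rows.append(("t1_cit100_fba", oracle_fba(t1, Medium("cit100", {"cit": 100}))))

    a, b = cross_feeder_pair()
    pair = assemble_community([a, b], Medium("glc10", {"glc": 10}))
    rows.append(("pair_no_limitation_total", oracle_community(pair, ObjectiveSpec.no_limitation())))
    rows.append(("pair_equal_abundance_mu", oracle_community(pair, ObjectiveSpec.equal_abundance())))
    rows.append(("pair_target_B", oracle_community(pair, ObjectiveSpec.target_strain("B"))))

    models, media = make_designed_consortium(dhp_spec())
    c2 = media[1]
    dh = assemble_community([models["d1"], models["h1"]], c2)
    rows.append(("dhp_DH_C2_total", oracle_community(dh, ObjectiveSpec.no_limitation())))

    out = Path(__file__).resolve().parent.parent / "tests" / "data" / "oracle_baseline.tsv"
    pd.DataFrame(rows, columns=["case", "oracle_value"]).to_csv(
        out, sep="\t", index=False, float_format="%.9f"
    )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
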