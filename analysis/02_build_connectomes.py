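"""Build per-subject connectivity matrices: Pearson FC from the time series
and morphometric similarity (MSN) from the five-feature tables."""

import numpy as np
from common import load_config, parse_args

from gradientscope import fc_matrix, io, msn_matrix


def main() -> None:
    args = parse_args(__doc__)
    cfg = load_config(args.config)
    scratch = cfg["paths"]["scratch"]
    manifest = io.read_manifest(scratch / "manifest.csv")

    for kind in ("fc", "msn"):
        (scratch / kind).mkdir(exist_ok=True)

    strengths = {"fc": [], "msn": []}
    for row in manifest.itertuples():
        series = io.read_series(scratch / row.timeseries_path)
        fc = fc_matrix(series, row.subject_id)
        np.savetxt(scratch / "fc" / f"{row.subject_id}.tsv", fc.values, delimiter="\t", fmt="%.6f")
        strengths["fc"].append(np.abs(fc.values).mean())

        feats = io.read_matrix(scratch / row.morphometry_path)
        msn = msn_matrix(feats, row.subject_id)
        np.savetxt(scratch / "msn" / f"{row.subject_id}.tsv", msn.values, delimiter="\t", fmt="%.6f")
        strengths["msn"].append(np.abs(msn.values).mean())

    for kind, vals in strengths.items():
        print(f"{kind.upper()}: {len(vals)} matrices, mean |connectivity| "
              f"{np.mean(vals):.3f} +- {np.std(vals):.3f}")


if __name__ == "__main__":
    main()
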