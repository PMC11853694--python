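"""Simulate the synthetic two-group cohort: time series, morphometry,
network partition and region coordinates.

Writes per-subject data under scratch/ (large, regenerated on demand) and
the small shared tables (manifest, partition, coordinates).  Gene
expression is generated later (05), planted against the measured
group-difference z-map.
"""

from common import load_config, parse_args, spec_from_config

from gradientscope import io, simulate_morphometry_cohort, simulate_timeseries_cohort
from gradientscope.synthcohort import region_coords


def main() -> None:
    args = parse_args(__doc__)
    cfg = load_config(args.config)
    spec = spec_from_config(cfg, args.seed)
    scratch = cfg["paths"]["scratch"]

    cohort = simulate_timeseries_cohort(spec)
    morpho = simulate_morphometry_cohort(spec)

    (scratch / "timeseries").mkdir(exist_ok=True)
    (scratch / "morphometry").mkdir(exist_ok=True)
    for sid, series in cohort.series.items():
        io.write_series(series, scratch / "timeseries" / f"{sid}.tsv")
    for sid, feats in morpho.features.items():
        io.write_matrix(feats, scratch / "morphometry" / f"{sid}.tsv")

    manifest = cohort.manifest.copy()
    manifest["timeseries_path"] = manifest["subject_id"].map(
        lambda s: f"timeseries/{s}.tsv"
    )
    manifest["morphometry_path"] = manifest["subject_id"].map(
        lambda s: f"morphometry/{s}.tsv"
    )
    io.write_manifest(manifest, scratch / "manifest.csv")
    io.write_partition(cohort.partition.labels, scratch / "partition.tsv")
    io.write_coords(region_coords(spec), scratch / "coords.tsv")

    n_con = (manifest["group"] == "control").sum()
    n_pat = (manifest["group"] == "patient").sum()
    print(f"cohort: {n_con} controls + {n_pat} patients, "
          f"{spec.n_regions} regions x {spec.n_timepoints} timepoints")
    print(f"planted: compression {spec.gradient_compression}, shifts {dict(spec.network_shift)}")
    print(f"written under {cfg['paths']['scratch']}")


if __name__ == "__main__":
    main()
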