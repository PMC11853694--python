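"""PLS association of the principal-gradient z-map with gene expression.

Expression is generated here, planted against the measured z-map (the map
this stage analyzes), so the transcriptomic machinery — PLS components,
spatially matched permutation inference, bootstrap-corrected gene weights,
VIP selection — is exercised against known ground truth.
"""

import pandas as pd
from common import load_config, parse_args, spec_from_config

from gradientscope import io
from gradientscope.plstx import (
    bootstrap_gene_weights,
    pls_fit,
    rank_genes,
    sa_permutation_test,
    score_map_correlation,
    vip_scores,
)
from gradientscope.synthcohort import make_gene_sets, simulate_expression


def main() -> None:
    args = parse_args(__doc__)
    cfg = load_config(args.config)
    scratch, results = cfg["paths"]["scratch"], cfg["paths"]["results"]

    zmap = pd.read_csv(results / "zmap.tsv", sep="\t")
    coords = io.read_coords(scratch / "coords.tsv")
    spec = spec_from_config(cfg, args.seed)
    n_comp = cfg["pls"]["n_components"]

    expr, signal = simulate_expression(spec, zmap["z"].to_numpy())
    io.write_matrix(expr, scratch / "expression.tsv")
    (scratch / "signal_genes.txt").write_text("\n".join(signal) + "\n")
    sets = make_gene_sets(
        signal, list(expr.columns), cfg["enrichment"]["n_sets"],
        cfg["enrichment"]["set_size"], seed=args.seed,
    )
    io.write_gmt(sets, scratch / "gene_sets.gmt")
    print(f"expression: {spec.n_genes} genes ({spec.n_signal_genes} signal, beta = "
          f"{spec.signal_beta}) planted against the measured z-map")

    fit = pls_fit(expr, zmap, n_components=n_comp)
    r = score_map_correlation(fit, zmap)
    perm = sa_permutation_test(
        expr, zmap, coords, n_components=n_comp,
        n_perm=cfg["pls"]["n_perm"], seed=args.seed,
    )
    boot = bootstrap_gene_weights(
        expr, zmap, n_components=n_comp, n_boot=cfg["pls"]["n_boot"], seed=args.seed
    )
    vip, selected = vip_scores(fit)

    for k in range(n_comp):
        print(f"component {k + 1}: cumulative R2 = {fit.r2_y_cumulative[k]:.3f} "
              f"({100 * fit.r2_y_cumulative[k]:.1f}%), score-map r = {r[k]:.3f}, "
              f"permutation p = {perm.perm_p[k]:.4f}")
    print(f"VIP > 1 selects {len(selected)} of {len(fit.gene_names)} genes")

    top_by_boot = set(rank_genes(boot, component=1)[: spec.n_signal_genes])
    print(f"planted-signal recovery: {len(top_by_boot & set(signal))}/{spec.n_signal_genes} "
          f"planted genes in the top-{spec.n_signal_genes} by |boot_z|; "
          f"{len(set(selected) & set(signal))}/{spec.n_signal_genes} among VIP-selected")

    table = pd.DataFrame(
        {
            "gene": fit.gene_names,
            "weight_1": fit.x_weights[:, 0],
            "weight_2": fit.x_weights[:, 1],
            "boot_z_1": boot.boot_z[:, 0],
            "boot_z_2": boot.boot_z[:, 1],
            "vip": vip,
            "selected": [g in set(selected) for g in fit.gene_names],
        }
    ).sort_values("boot_z_1", key=abs, ascending=False)
    table.to_csv(results / "gene_table.tsv", sep="\t", index=False)

    io.write_json(
        {
            "r2_y_cumulative": fit.r2_y_cumulative.tolist(),
            "score_map_r": r.tolist(),
            "perm_p": perm.perm_p.tolist(),
            "n_selected_vip": len(selected),
            "n_perm": cfg["pls"]["n_perm"],
            "n_boot": cfg["pls"]["n_boot"],
        },
        results / "pls_summary.json",
    )
    print(f"gene table -> {results / 'gene_table.tsv'}; summary -> {results / 'pls_summary.json'}")


if __name__ == "__main__":
    main()
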