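"""End-to-end orchestration: discovery matrix -> QC -> differential ->
panels -> normalizers -> MRM transition lists.

Statistics run on biological-replicate (BR) columns only; SR/TR injections
feed the CV gate but are not treated as independent samples.
"""

from __future__ import annotations

import os

import pandas as pd

from . import mrm as mrm_mod
from . import normalize, panel, qc, simulate, stats
from .matrix import IntensityMatrix


def hx_contrasts(m: IntensityMatrix) -> list[tuple[str, list[str], list[str]]]:
    """Per cell line x timepoint treated-vs-control BR contrasts."""
    design = m.design.loc[list(m.samples)]
    br = design[design["rep_kind"] == "BR"]
    treatments = list(dict.fromkeys(br["treatment"]))
    control = treatments[-1]
    treated = [t for t in treatments if t != control]
    out = []
    for line in dict.fromkeys(br["cell_line"]):
        for tp in dict.fromkeys(br["timepoint"]):
            for treat in treated:
                a = br[(br.cell_line == line) & (br.timepoint == tp) & (br.treatment == treat)]
                b = br[(br.cell_line == line) & (br.timepoint == tp) & (br.treatment == control)]
                if len(a) >= 2 and len(b) >= 2:
                    label = f"{line} {treat}-vs-{control} {tp}"
                    out.append((label, list(a.index), list(b.index)))
    return out


def as_groups(m: IntensityMatrix, as_lines: list[str] | None = None) -> dict[str, list[str]]:
    """Androgen-sensitive vs androgen-independent BR sample partition."""
    design = m.design.loc[list(m.samples)]
    br = design[design["rep_kind"] == "BR"]
    lines = list(dict.fromkeys(br["cell_line"]))
    as_lines = as_lines or lines[:1]
    return {
        "AS": list(br.index[br["cell_line"].isin(as_lines)]),
        "AI": list(br.index[~br["cell_line"].isin(as_lines)]),
    }


def run_differential(
    m: IntensityMatrix,
    cfg: stats.AnalysisConfig | None = None,
    as_lines: list[str] | None = None,
) -> dict:
    """Transform + impute, then Hx t-tests and the AS-vs-AI ANOVA."""
    cfg = cfg or stats.AnalysisConfig()
    logged = stats.log2_transform(m)
    imputed = stats.impute_constant(logged, cfg)

    ttables = [
        stats.ttest_contrast(imputed, a, b, cfg, contrast=label)
        for label, a, b in hx_contrasts(imputed)
    ]
    hx = pd.concat(ttables, ignore_index=True) if ttables else pd.DataFrame(columns=stats.RESULT_COLUMNS)
    anova = stats.anova_all_groups(imputed, as_groups(imputed, as_lines), cfg, contrast="AS-vs-AI ANOVA")
    return {"imputed": imputed, "hx": hx, "as": anova}


def run_pipeline(
    out_dir: str,
    config: simulate.SimulationConfig | None = None,
    cfg: stats.AnalysisConfig | None = None,
    cv_max: float = 20.0,
    score_threshold: int = 2,
) -> dict[str, str]:
    """Simulate a study and run every stage, writing all artifacts.

    Returns a name -> path map of the written files.
    """
    config = config or simulate.SimulationConfig()
    cfg = cfg or stats.AnalysisConfig()
    os.makedirs(out_dir, exist_ok=True)

    truth = simulate.simulate_catalog(config)
    matrix = simulate.simulate_matrix(truth, config)
    fixture_dir = os.path.join(out_dir, "inputs")
    paths = simulate.write_fixtures(truth, matrix, fixture_dir)

    m = qc.read_protein_groups(paths["protein_groups"], paths["design"])
    m = qc.filter_identifications(m)
    paths.update(qc.write_qc_report(m, out_dir))
    cv = qc.compute_cv(m)

    diff = run_differential(m, cfg)
    differential = pd.concat([diff["hx"], diff["as"].table], ignore_index=True)
    paths["differential"] = os.path.join(out_dir, "differential.tsv")
    differential.to_csv(paths["differential"], sep="\t", index=False)

    pca_res = stats.pca(diff["imputed"], n_components=5)
    paths["pca_scores"] = os.path.join(out_dir, "pca_scores.tsv")
    pca_res.scores.rename_axis("sample").to_csv(paths["pca_scores"], sep="\t")

    significant = sorted(set(differential.loc[differential["significant"], "protein"]))
    if len(significant) >= 2:
        tree = stats.cluster_significant(diff["imputed"], significant, cfg)
        paths["newick"] = os.path.join(out_dir, "significant_clusters.nwk")
        with open(paths["newick"], "w") as fh:
            fh.write(tree.newick + "\n")

    annotations = panel.read_annotations(paths["annotations"])
    selected_proteins: list[str] = []
    for kind, table in (("Hx", diff["hx"]), ("AS", diff["as"].table)):
        cands = panel.assemble_candidates(table, cv, kind, cv_max, annotations=annotations)
        chosen = panel.select_panel(cands, threshold=score_threshold)
        frame = panel.panel_to_frame(chosen)
        key = f"panel_{kind.lower()}"
        paths[key] = os.path.join(out_dir, f"{key}.tsv")
        frame.to_csv(paths[key], sep="\t", index=False)
        selected_proteins.extend(c.protein for c in chosen)

    hk_list = normalize.read_housekeeping_list(paths["housekeeping"])
    try:
        sel = normalize.select_housekeeping(m, hk_list, cv)
        paths["housekeeping_selection"] = os.path.join(out_dir, "housekeeping_selection.tsv")
        sel.table.to_csv(paths["housekeeping_selection"], sep="\t")
    except ValueError:
        sel = None

    fasta = mrm_mod.read_fasta(paths["fasta"])
    library = mrm_mod.read_library(paths["library"])
    assay_targets = sorted(set(selected_proteins)) or sorted(fasta)[:10]
    if sel is not None:
        assay_targets = sorted(set(assay_targets) | set(sel.proteins))
    assay = mrm_mod.design_assay(assay_targets, fasta, library)
    paths["transitions"] = os.path.join(out_dir, "transitions.csv")
    assay.to_csv(paths["transitions"])
    paths["design_failures"] = os.path.join(out_dir, "design_failures.tsv")
    assay.failures.to_csv(paths["design_failures"], sep="\t", index=False)
    return paths
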