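"""Transcriptome-wide expression pattern: TMM normalization, the TPM
expression filter, and leading-logFC MDS of all samples and of each tissue.

Expected picture: samples separate by tissue first, then by parental
species, with each autotetraploid mixed among its diploid progenitors and
the three hybrid groups sitting together between the parents.

Writes TMM factors, the expressed-gene list, and MDS coordinates under
results/ordination/.
"""

from _shared import RESULTS, load_experiment

from allohybrid import core, normalize, ordination
from allohybrid.core import AnalysisThresholds

OUT = RESULTS / "ordination"


def mds_coordinates(counts, thresholds, tissue=None):
    sub = (counts if tissue is None
           else counts.subset_samples(counts.samples["tissue"] == tissue))
    tpm = normalize.compute_tpm(sub)
    expressed = normalize.filter_expressed(
        tpm, thresholds.min_tpm, thresholds.min_tpm_samples)
    kept = sub.subset_features(expressed)
    eff = normalize.effective_library_sizes(kept, thresholds)
    logcpm = normalize.compute_cpm(kept, prior=thresholds.cpm_prior_count,
                                   effective_sizes=eff, log=True)
    res = ordination.mds(logcpm, top=min(thresholds.mds_top_genes, len(expressed)))
    return res, expressed


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts, _, _ = load_experiment()
    thr = AnalysisThresholds()

    res_all, expressed = mds_coordinates(counts, thr)
    core.write_table(
        expressed.to_frame(index=False, name="feature_id"),
        OUT / "expressed_genes.tsv")
    print(f"{len(expressed)} genes pass TPM > {thr.min_tpm:g} "
          f"in >= {thr.min_tpm_samples} samples")

    factors = normalize.tmm_factors(counts, thr)
    core.write_table(factors.rename_axis("sample_id").reset_index(),
                     OUT / "tmm_factors.tsv")

    coords = res_all.coordinates.join(counts.samples[["group", "tissue"]])
    core.write_table(coords.rename_axis("sample_id").reset_index(),
                     OUT / "mds_all_samples.tsv")
    by_tissue = coords.groupby("tissue")["dim1"].mean()
    print("dim1 tissue separation (group means):", by_tissue.round(2).to_dict())

    for tissue in ("flower", "leaf"):
        res_t, _ = mds_coordinates(counts, thr, tissue)
        ct = res_t.coordinates.join(counts.samples[["group"]])
        core.write_table(ct.rename_axis("sample_id").reset_index(),
                         OUT / f"mds_{tissue}.tsv")
        d = res_t.distance_matrix
        s = counts.samples[counts.samples["tissue"] == tissue]

        def mean_dist(g1, g2):
            return float(d.loc[s.index[s["group"] == g1],
                               s.index[s["group"] == g2]].to_numpy().mean())

        print(f"{tissue}: d(Co2,Co4)={mean_dist('Co2', 'Co4'):.3f}  "
              f"d(Cg2,Cg4)={mean_dist('Cg2', 'Cg4'):.3f}  "
              f"d(Co2,Cg2)={mean_dist('Co2', 'Cg2'):.3f}  "
              "(autotetraploids sit with their diploids)")


if __name__ == "__main__":
    main()
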