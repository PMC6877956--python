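# Published per-ligand cross-validation metrics of the SmoPSI predictor on the
# 14 sc-PDB ligand classes (10-fold CV, window width 15). Per-ligand rows only;
# the Average row is recomputed by evaluation.aggregate_report.
ligand	ACC	precision	recall	F1	AUC
ACO	0.900	0.886	0.921	0.904	0.891
ADP	0.910	0.891	0.934	0.912	0.927
ANP	0.900	0.863	0.940	0.900	0.897
ATP	0.927	0.914	0.940	0.927	0.935
COA	0.928	0.918	0.940	0.929	0.931
FAD	0.903	0.875	0.932	0.903	0.917
FMN	0.926	0.911	0.940	0.925	0.932
GDP	0.929	0.917	0.940	0.928	0.937
GNP	0.926	0.914	0.940	0.927	0.925
NAD	0.916	0.898	0.937	0.917	0.922
NAP	0.915	0.893	0.940	0.916	0.912
NDP	0.906	0.875	0.940	0.907	0.908
SAH	0.875	0.830	0.930	0.877	0.894
SAM	0.926	0.914	0.940	0.927	0.920
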