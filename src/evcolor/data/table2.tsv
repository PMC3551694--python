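# Published eye and hair colour prediction results for the 26 skeletal
# samples: per-category probabilities, inferred colours, and the accuracy
# annotations (hair accuracies from a >300-individual European test set, eye
# accuracies from a >3,800-individual European test set).  Transcribed by
# hand from the published per-sample blocks into one row per sample.
# Probabilities are printed to 3 decimals; category blocks therefore sum to
# 1 only within rounding (tolerance 0.011).  "-" = hair prediction withheld
# (S25: too many hair-model genotypes missing).  Accuracies in percent.
sample_id	hair_brown	hair_red	hair_black	hair_blond	shade_light	shade_dark	hair_call	hair_accuracy	eye_blue	eye_intermediate	eye_brown	eye_call	eye_accuracy
S1	0.367	0.002	0.499	0.133	0.268	0.732	Dark Brown	78.5	0.317	0.193	0.490	Brown	87.5
S2	0.246	0.001	0.326	0.427	0.655	0.345	Dark Blond/Brown	78.5	0.306	0.142	0.552	Brown	91
S3	0.496	0.001	0.406	0.098	0.215	0.785	Dark Brown	78.5	0.190	0.271	0.539	Brown	90.4
S4	0.064	0.048	0.025	0.864	0.976	0.024	Light Blond	69.5	0.919	0.048	0.033	Blue	97.4
S5	0.251	0.000	0.729	0.020	0.020	0.980	Black/Dark Brown	87.5	0.706	0.117	0.177	Blue	94
S6	0.227	0.000	0.636	0.136	0.171	0.829	Dark Brown	78.5	0.002	0.026	0.972	Brown	99
S7	0.282	0.000	0.690	0.028	0.030	0.970	Black/Dark Brown	87.5	0.706	0.117	0.177	Blue	94
S8	0.246	0.000	0.594	0.160	0.196	0.804	Dark Brown	78.5	0.024	0.083	0.892	Brown	95.6
S9	0.324	0.001	0.538	0.136	0.212	0.788	Dark Brown	78.5	0.911	0.057	0.032	Blue	97.4
S10	0.153	0.000	0.829	0.017	0.016	0.984	Black	87.5	0.001	0.016	0.983	Brown	99
S11	0.076	0.037	0.035	0.852	0.964	0.036	Light Blond	69.5	0.950	0.030	0.020	Blue	99
S12	0.044	0.090	0.049	0.817	0.969	0.031	Light Blond	69.5	0.937	0.041	0.022	Blue	97.4
S13	0.180	0.025	0.119	0.676	0.883	0.117	Dark Blond/Light Brown	69.5	0.229	0.128	0.643	Brown	91.9
S14	0.157	0.005	0.072	0.766	0.907	0.093	Light Blond	69.5	0.899	0.066	0.035	Blue	95.6
S15	0.168	0.004	0.064	0.765	0.927	0.073	Light Blond	69.5	0.870	0.076	0.053	Blue	95.6
S16	0.089	0.002	0.054	0.856	0.951	0.049	Light Blond	69.5	0.950	0.030	0.020	Blue	99
S17	0.221	0.001	0.263	0.514	0.696	0.304	Dark Blond/Brown	78.5	0.207	0.161	0.632	Brown	91.9
S18	0.083	0.090	0.024	0.802	0.969	0.031	Light Blond	69.5	0.937	0.041	0.022	Blue	97.4
S19	0.075	0.002	0.039	0.883	0.968	0.032	Light Blond	69.5	0.950	0.030	0.020	Blue	99
S20	0.246	0.001	0.183	0.570	0.727	0.273	Dark Blond/Brown	78.5	0.207	0.161	0.632	Brown	91.9
S21	0.089	0.002	0.054	0.856	0.951	0.049	Light Blond	69.5	0.937	0.041	0.022	Blue	97.4
S22	0.155	0.008	0.053	0.783	0.934	0.066	Light Blond	69.5	0.870	0.076	0.053	Blue	95.6
S23	0.218	0.002	0.248	0.532	0.696	0.304	Dark Blond/Brown	78.5	0.150	0.140	0.711	Brown	94
S24	0.202	0.002	0.301	0.495	0.695	0.305	Dark Blond/Brown	78.5	0.277	0.179	0.543	Brown	90.4
S25	-	-	-	-	-	-	-	-	0.899	0.066	0.035	Blue	95.6
S26	0.131	0.007	0.078	0.784	0.918	0.082	Light Blond	69.5	0.919	0.048	0.033	Blue	97.4
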