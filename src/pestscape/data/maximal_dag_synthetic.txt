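# Maximal DAG over the GB tree pest/disease covariates.
#
# SYNTHETIC RECONSTRUCTION: the published graph exists only as a figure, so
# this edge list is a plausible transcription assembled from the figure
# caption's variable list and the textual driver discussion. Edit freely —
# the analysis treats this file as configuration.
#
# Nodes: E elevation, d_G distance to park/garden, d_BCP distance to border
# control post, VPD vapour pressure deficit, H human population, Ur urban
# area, Af afforestation, Df deforestation, A ancient woodland area,
# C_a conifer area, B_a broadleaf area, W_a woodland area, W_c woodland
# connectivity, R recreation; latent p_i (introduction probability),
# p_e (establishment probability); outcome y (pest/disease occurrence).

E -> VPD
E -> H
E -> R
E -> p_e
VPD -> p_e
H -> Ur
H -> R
H -> p_i
Ur -> p_i
R -> p_i
d_G -> R
d_G -> p_i
d_BCP -> p_i
Af -> W_a
Af -> p_i
Df -> W_a
Df -> p_i
A -> W_a
A -> p_e
C_a -> W_a
C_a -> p_e
B_a -> W_a
B_a -> p_e
W_a -> W_c
W_c -> p_i
W_c -> p_e
p_i -> y
p_e -> y
latent: p_i, p_e
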