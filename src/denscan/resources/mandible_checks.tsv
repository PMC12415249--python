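# Mandibular prediction checks for the two molecularly confirmed Denisovan
# mandibles (Xiahe 1, Penghu 1): five measurements carrying six directional
# predictions each. evidence_type is "numeric" when both the observed and the
# comparator values are printed, "reported_relation" when only the published
# qualitative relation (greater/less than the comparator) is available, and
# "missing" when the element or measurement is unavailable. predicted_direction
# is +1 when the Denisovan profile predicts the larger value.
specimen	prediction_id	measurement	predicted_direction	comparator_group	comparator_kind	evidence_type	observed_value	comparator_value	relation	units	note
XIAHE_1	mandibular_prognathism	superior_mandibular_length	1	early_H_sapiens	median	missing	NA	NA	NA	mm	measurement not available for Xiahe 1
XIAHE_1	anterior_mandibular_width	bicanine_breadth	1	early_H_sapiens	median	reported_relation	NA	NA	greater	mm	published relation only
XIAHE_1	anterior_mandibular_height	symphyseal_height	1	early_H_sapiens	median	reported_relation	NA	NA	greater	mm	published relation only
XIAHE_1	condylar_size	condylar_head_area	1	modern_male	mean	missing	NA	NA	NA	mm2	condyle of Xiahe 1 is missing
XIAHE_1	dental_arch_length_vs_AMH	dental_arcade_length	1	AMH_weighted	mean	numeric	55.7	52.58	NA	mm	AMH comparator is a weighted mean across H. sapiens groups
XIAHE_1	dental_arch_length_vs_NEA	dental_arcade_length	1	NEA_weighted	mean	numeric	55.7	54.78	NA	mm	Neanderthal comparator is a weighted mean of Asian and European Neanderthals
PENGHU_1	mandibular_prognathism	superior_mandibular_length	1	early_H_sapiens	median	reported_relation	NA	NA	greater	mm	published relation only
PENGHU_1	anterior_mandibular_width	bicanine_breadth	1	early_H_sapiens	median	reported_relation	NA	NA	greater	mm	published relation only
PENGHU_1	anterior_mandibular_height	symphyseal_height	1	early_H_sapiens	median	reported_relation	NA	NA	less	mm	observed shorter; contradicts the prediction
PENGHU_1	condylar_size	condylar_head_area	1	modern_male	mean	numeric	189.34	133.63	NA	mm2	area approximated as an ellipse from the mediolateral and anteroposterior condylar dimensions
PENGHU_1	dental_arch_length_vs_AMH	dental_arcade_length	1	early_H_sapiens	median	reported_relation	NA	NA	greater	mm	inferred from arcade index and incisal/premolar widths
PENGHU_1	dental_arch_length_vs_NEA	dental_arcade_length	1	NEA_weighted	median	reported_relation	NA	NA	greater	mm	inferred from arcade index and incisal/premolar widths
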