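# Calibration-node stub for the 13 fungal fossil constraints (nodes A-M).
# Only the worked minimum printed in the source methods is filled in
# (Rhynie Chert: Lower Devonian lower boundary 407.0 Ma minus 2.8 Ma margin).
# Normal-component mean/sd (param1/param2 for truncated_normal) are user inputs.
fossil_name	clade_name	stage_lower_bound_ma	margin_my	prior_family	param1	param2
rhynie_chert_A	node_A	407.0	2.8	truncated_normal	NA	NA
fossil_B	node_B	NA	NA	truncated_normal	NA	NA
fossil_C	node_C	NA	NA	truncated_normal	NA	NA
fossil_D	node_D	NA	NA	truncated_normal	NA	NA
fossil_E	node_E	NA	NA	truncated_normal	NA	NA
fossil_F	node_F	NA	NA	truncated_normal	NA	NA
fossil_G	node_G	NA	NA	truncated_normal	NA	NA
fossil_H	node_H	NA	NA	truncated_normal	NA	NA
fossil_I	node_I	NA	NA	truncated_normal	NA	NA
fossil_J	node_J	NA	NA	truncated_normal	NA	NA
fossil_K	node_K	NA	NA	truncated_normal	NA	NA
fossil_L	node_L	NA	NA	truncated_normal	NA	NA
fossil_M	node_M	NA	NA	truncated_normal	NA	NA
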