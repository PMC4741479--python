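mirna_id	direction
hsa-mir-016	up
hsa-mir-029b	up
hsa-mir-150	up
hsa-miR-1254	up
hsa-let-7e	down
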