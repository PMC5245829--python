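# transcript_id	utr3_start (0-based)
LBP_like	400
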