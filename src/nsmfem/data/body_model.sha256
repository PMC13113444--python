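313243de523959ea7d33d5c320ddafd6136d6c884e66b3f6fe8460cdb8cf47cb  body_model.json
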