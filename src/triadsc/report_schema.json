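{
  "title": "triadsc run report",
  "required": {
    "version": "string",
    "status": "string",
    "steps": "object",
    "outputs": "object",
    "counts": "object",
    "thresholds": "object"
  }
}
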