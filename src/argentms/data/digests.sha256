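5d667b672281ec2151cb422d1c9136a1c007ac6a2eb1327c741e546eb0f7b456  table2.tsv
0a123587df8666f5636b8630863c5a792ccbc5a6527bd62dbad7cd1b91909a69  table3.tsv
f231467385e4c32c0182588b040e72d3b8feeb878091020ae4802f40be3c1b09  table4.tsv
0e2592f8695d2498acc005cd97d5bc5b60d4856812d7ed301b0dcc7e069f1b4f  class_shares.tsv
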