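family	unified_name	paralogs	zinc_annotated
RPL34	eL34	A;B	no
RPL37	eL37	A;B	yes
RPL40	eL40	A;B	yes
RPL42	eL42	A;B	yes
RPL43	eL43	A;B	yes
RPS26	eS26	A;B	yes
RPS27	eS27	A;B	yes
RPS29	uS14	A;B	yes
RPS31	eS31		yes
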