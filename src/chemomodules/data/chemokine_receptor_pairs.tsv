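ligand	receptor	source
CCL1	CCR8	curated
CCL2	CCR2	curated
CCL3	CCR1	curated
CCL3	CCR5	curated
CCL4	CCR5	curated
CCL5	CCR1	curated
CCL5	CCR3	curated
CCL5	CCR5	curated
CCL7	CCR1	curated
CCL7	CCR2	curated
CCL7	CCR3	curated
CCL8	CCR1	curated
CCL8	CCR2	curated
CCL8	CCR3	curated
CCL8	CCR5	curated
CCL11	CCR3	curated
CCL13	CCR2	curated
CCL13	CCR3	curated
CCL14	CCR1	curated
CCL15	CCR1	curated
CCL15	CCR3	curated
CCL16	CCR1	curated
CCL16	CCR2	curated
CCL17	CCR4	curated
CCL19	CCR7	curated
CCL20	CCR6	curated
CCL21	CCR7	curated
CCL22	CCR4	curated
CCL23	CCR1	curated
CCL24	CCR3	curated
CCL25	CCR9	curated
CCL26	CCR3	curated
CCL27	CCR10	curated
CCL28	CCR3	curated
CCL28	CCR10	curated
CXCL1	CXCR2	curated
CXCL2	CXCR2	curated
CXCL3	CXCR2	curated
CXCL5	CXCR2	curated
CXCL6	CXCR1	curated
CXCL6	CXCR2	curated
CXCL8	CXCR1	curated
CXCL8	CXCR2	curated
CXCL9	CXCR3	curated
CXCL10	CXCR3	curated
CXCL11	CXCR3	curated
CXCL11	ACKR3	curated
CXCL12	CXCR4	curated
CXCL12	ACKR3	curated
CXCL13	CXCR5	curated
CXCL16	CXCR6	curated
CX3CL1	CX3CR1	curated
XCL1	XCR1	curated
XCL2	XCR1	curated
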