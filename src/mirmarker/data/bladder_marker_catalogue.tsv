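name	status	type	references	note
mir141	CONTRADICTORY	EXPRESSION	Billerey 2001|Adachi 2011	reported both ways
mir205	CONTRADICTORY	EXPRESSION	Gottardo 2007|Dyrskjot 2009|Tao 2011|Catto 2009|Wiklund 2011	reported both ways
mir100	CONTRADICTORY	EXPRESSION	Catto 2009	FGFR3 pathway
mir200a	CONTRADICTORY	EXPRESSION	literature survey	
mir203	CONTRADICTORY	EXPRESSION	literature survey	
mir10	CONTRADICTORY	EXPRESSION	Veerla 2009	p53 pathway
mir21	UP	EXPRESSION	literature survey	
mir183	UP	EXPRESSION	literature survey	
mir199b	UP	EXPRESSION	Gottardo 2007	
mir26b	UP	EXPRESSION	Veerla 2009	
mir103	UP	EXPRESSION	literature survey	
mir222	UP	EXPRESSION	Veerla 2009	p53 pathway
mir96	UP	EXPRESSION	literature survey	
mir20a	UP	EXPRESSION	literature survey	
mir106b	UP	EXPRESSION	literature survey	
mir130b	UP	EXPRESSION	literature survey	
mir200b	UP	EXPRESSION	literature survey	
mir200c	UP	EXPRESSION	literature survey	
mir429	UP	EXPRESSION	literature survey	
mir17	UP	EXPRESSION	literature survey	
mir18a	UP	EXPRESSION	literature survey	
mir19a	UP	EXPRESSION	literature survey	
mir210	UP	EXPRESSION	literature survey	
mir182	UP	EXPRESSION	literature survey	
mir224	UP	EXPRESSION	literature survey	
mir143	DOWN	EXPRESSION	Lin 2009|Kent 2010	FGFR3 pathway
mir199a	DOWN	EXPRESSION	literature survey	
mir199a2	DOWN	EXPRESSION	literature survey	
mir126	DOWN	EXPRESSION	Saito 2009	
mir146a	DOWN	EXPRESSION	literature survey	
mir34a	DOWN	METHYLATION_HYPER	Lodygin 2008	p53 pathway; also reported down-regulated
mir493	DOWN	EXPRESSION	Ueno 2011	
mir125b	DOWN	EXPRESSION	Veerla 2009	p53 pathway
let7c	DOWN	EXPRESSION	literature survey	
mir145	DOWN	EXPRESSION	Catto 2009	FGFR3 pathway
mir101	DOWN	EXPRESSION	Catto 2009	FGFR3 pathway
mir99a	DOWN	EXPRESSION	Catto 2009	FGFR3 pathway
mir7	DOWN	EXPRESSION	literature survey	FGFR3 pathway
mir129	DOWN	EXPRESSION	Fendler 2012	p53 pathway
mir223	DOWN	EXPRESSION	Fendler 2012	p53 pathway
mir29c	DOWN	EXPRESSION	literature survey	
mir30a	DOWN	EXPRESSION	literature survey	
mir30c	DOWN	EXPRESSION	literature survey	
mir133a	DOWN	EXPRESSION	literature survey	
mir133b	DOWN	EXPRESSION	literature survey	
mir195	DOWN	EXPRESSION	literature survey	
mir744	UP	METHYLATION_HYPO	Martin 2011	TGF-beta1 regulation
mir9001	UP	EXPRESSION	synthetic	synthetic filler
mir9002	DOWN	EXPRESSION	synthetic	synthetic filler
mir9003	UP	EXPRESSION	synthetic	synthetic filler
mir9004	DOWN	EXPRESSION	synthetic	synthetic filler
mir9005	UP	EXPRESSION	synthetic	synthetic filler
mir9006	DOWN	EXPRESSION	synthetic	synthetic filler
mir9007	UP	EXPRESSION	synthetic	synthetic filler
mir9008	DOWN	EXPRESSION	synthetic	synthetic filler
mir9009	UP	EXPRESSION	synthetic	synthetic filler
mir9010	DOWN	EXPRESSION	synthetic	synthetic filler
mir9011	UP	EXPRESSION	synthetic	synthetic filler
mir9012	DOWN	EXPRESSION	synthetic	synthetic filler
mir9013	UP	EXPRESSION	synthetic	synthetic filler
mir9014	DOWN	EXPRESSION	synthetic	synthetic filler
mir9015	UP	EXPRESSION	synthetic	synthetic filler
mir9016	DOWN	EXPRESSION	synthetic	synthetic filler
mir9017	UP	EXPRESSION	synthetic	synthetic filler
mir9018	DOWN	EXPRESSION	synthetic	synthetic filler
mir9019	UP	EXPRESSION	synthetic	synthetic filler
mir9020	DOWN	EXPRESSION	synthetic	synthetic filler
mir9021	UP	EXPRESSION	synthetic	synthetic filler
mir9022	DOWN	EXPRESSION	synthetic	synthetic filler
mir9023	UP	EXPRESSION	synthetic	synthetic filler
mir9024	DOWN	EXPRESSION	synthetic	synthetic filler
mir9025	UP	EXPRESSION	synthetic	synthetic filler
mir9026	DOWN	EXPRESSION	synthetic	synthetic filler
mir9027	UP	EXPRESSION	synthetic	synthetic filler
mir9028	DOWN	EXPRESSION	synthetic	synthetic filler
mir9029	UP	EXPRESSION	synthetic	synthetic filler
mir9030	DOWN	EXPRESSION	synthetic	synthetic filler
mir9031	UP	EXPRESSION	synthetic	synthetic filler
mir9032	DOWN	EXPRESSION	synthetic	synthetic filler
mir9033	UP	EXPRESSION	synthetic	synthetic filler
mir9034	DOWN	EXPRESSION	synthetic	synthetic filler
mir9035	UP	EXPRESSION	synthetic	synthetic filler
mir9036	DOWN	EXPRESSION	synthetic	synthetic filler
mir9037	UP	EXPRESSION	synthetic	synthetic filler
mir9038	DOWN	EXPRESSION	synthetic	synthetic filler
mir9039	UP	EXPRESSION	synthetic	synthetic filler
mir9040	DOWN	EXPRESSION	synthetic	synthetic filler
mir9041	UP	EXPRESSION	synthetic	synthetic filler
mir9042	DOWN	EXPRESSION	synthetic	synthetic filler
mir9043	UP	EXPRESSION	synthetic	synthetic filler
mir9044	DOWN	EXPRESSION	synthetic	synthetic filler
mir9045	UP	EXPRESSION	synthetic	synthetic filler
mir9046	DOWN	EXPRESSION	synthetic	synthetic filler
mir9047	UP	EXPRESSION	synthetic	synthetic filler
mir9048	DOWN	EXPRESSION	synthetic	synthetic filler
mir9049	UP	EXPRESSION	synthetic	synthetic filler
mir9050	DOWN	EXPRESSION	synthetic	synthetic filler
mir9501	UP	METHYLATION_HYPO	synthetic	synthetic filler
mir9502	DOWN	METHYLATION_HYPER	synthetic	synthetic filler
mir9503	UP	METHYLATION_HYPO	synthetic	synthetic filler
mir9504	DOWN	METHYLATION_HYPER	synthetic	synthetic filler
mir9505	UP	METHYLATION_HYPO	synthetic	synthetic filler
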