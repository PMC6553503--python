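locus_id	category	partner_id	family	target_pcc
TFS001	singleton		FAMS001	
TFS002	singleton		FAMS002	
TFS003	singleton		FAMS003	
TFS004	singleton		FAMS004	
TFS005	singleton		FAMS005	
TFS006	singleton		FAMS006	
TFS007	singleton		FAMS007	
TFS008	singleton		FAMS008	
TFS009	singleton		FAMS009	
TFS010	singleton		FAMS010	
TFS011	singleton		FAMS011	
TFS012	singleton		FAMS012	
TFS013	singleton		FAMS013	
TFS014	singleton		FAMS014	
TFS015	singleton		FAMS015	
TFS016	singleton		FAMS016	
TFS017	singleton		FAMS017	
TFS018	singleton		FAMS018	
TFS019	singleton		FAMS019	
TFS020	singleton		FAMS020	
TFS021	singleton		FAMS021	
TFS022	singleton		FAMS022	
TFS023	singleton		FAMS023	
TFS024	singleton		FAMS024	
TFS025	singleton		FAMS025	
TFS026	singleton		FAMS026	
TFS027	singleton		FAMS027	
TFS028	singleton		FAMS028	
TFS029	singleton		FAMS029	
TFS030	singleton		FAMS030	
TFS031	singleton		FAMS031	
TFS032	singleton		FAMS032	
TFS033	singleton		FAMS033	
TFS034	singleton		FAMS034	
TFS035	singleton		FAMS035	
TFS036	singleton		FAMS036	
TFS037	singleton		FAMS037	
TFS038	singleton		FAMS038	
TFS039	singleton		FAMS039	
TFN001	no_probe	PARN001	FAMN001	
TFN002	no_probe	PARN002	FAMN002	
TFN003	no_probe	PARN003	FAMN003	
TFN004	no_probe	PARN004	FAMN004	
TFN005	no_probe	PARN005	FAMN005	
TFN006	no_probe	PARN006	FAMN006	
TFN007	no_probe	PARN007	FAMN007	
TFN008	no_probe	PARN008	FAMN008	
TFN009	no_probe	PARN009	FAMN009	
TFN010	no_probe	PARN010	FAMN010	
TFN011	no_probe	PARN011	FAMN011	
TFN012	no_probe	PARN012	FAMN012	
TFN013	no_probe	PARN013	FAMN013	
TFN014	no_probe	PARN014	FAMN014	
Ehd3	pair	LOC_Os01g66070	PHD	-0.09
LOC_Os09g31310	pair	LOC_Os02g48650	GNAT	0.24
OsMADS8	pair	OsMADS7	MADS	0.92
TFP001	pair	PARP001	FAMP001	-0.125
TFP002	pair	PARP002	FAMP002	-0.125
TFP003	pair	PARP003	FAMP003	-0.125
TFP004	pair	PARP004	FAMP004	0.125
TFP005	pair	PARP005	FAMP005	0.125
TFP006	pair	PARP006	FAMP006	0.125
TFP007	pair	PARP007	FAMP007	0.125
TFP008	pair	PARP008	FAMP008	0.125
TFP009	pair	PARP009	FAMP009	0.125
TFP010	pair	PARP010	FAMP010	0.125
TFP011	pair	PARP011	FAMP011	0.125
TFP012	pair	PARP012	FAMP012	0.125
TFP013	pair	PARP013	FAMP013	0.125
TFP014	pair	PARP014	FAMP014	0.375
TFP015	pair	PARP015	FAMP015	0.375
TFP016	pair	PARP016	FAMP016	0.375
TFP017	pair	PARP017	FAMP017	0.375
TFP018	pair	PARP018	FAMP018	0.375
TFP019	pair	PARP019	FAMP019	0.375
TFP020	pair	PARP020	FAMP020	0.375
TFP021	pair	PARP021	FAMP021	0.375
TFP022	pair	PARP022	FAMP022	0.375
TFP023	pair	PARP023	FAMP023	0.375
TFP024	pair	PARP024	FAMP024	0.375
TFP025	pair	PARP025	FAMP025	0.625
TFP026	pair	PARP026	FAMP026	0.625
TFP027	pair	PARP027	FAMP027	0.625
TFP028	pair	PARP028	FAMP028	0.625
TFP029	pair	PARP029	FAMP029	0.625
TFP030	pair	PARP030	FAMP030	0.625
TFP031	pair	PARP031	FAMP031	0.625
TFP032	pair	PARP032	FAMP032	0.625
TFP033	pair	PARP033	FAMP033	0.625
TFP034	pair	PARP034	FAMP034	0.625
TFP035	pair	PARP035	FAMP035	0.875
TFP036	pair	PARP036	FAMP036	0.875
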